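"""Sliding-window coincidence statistic and its jitter correction."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gammasync import (CouplingScenario, EventTable, SpikeTrain,
                       SynchronyParams, coincidence_series,
                       event_triggered_synchrony, generate_session,
                       jitter_correct, pool_trains, synchrony_series)
from gammasync.spikesync import boxcar_smooth, jitter_spikes
from .conftest import poisson_train


def brute_force_coincidences(v1_times, lgn_times, grid, params):
    """Pair-enumeration oracle: count (V1, shifted-dLGN) spike pairs that
    fall together inside each half-open window."""
    half_w = params.window_ms / 2000.0
    shifted = lgn_times + params.delay_ms / 1000.0
    out = np.zeros(grid.size)
    for i, t in enumerate(grid):
        lo, hi = t - half_w, t + half_w
        for a in v1_times:
            if lo <= a < hi:
                for b in shifted:
                    if lo <= b < hi:
                        out[i] += 1
    return out


class TestCoincidenceSeries:
    def test_single_aligned_pair(self):
        p = SynchronyParams()
        v1 = SpikeTrain([0.100], span=(0.0, 0.3))
        lgn = SpikeTrain([0.095], span=(0.0, 0.3))
        times, raw = coincidence_series(v1, lgn, p)
        # shifted dLGN spike lands exactly on the V1 spike
        covering = (times > 0.100 - 0.00225) & (times <= 0.100 + 0.00225)
        assert np.all(raw[covering] == 1)
        assert np.all(raw[~covering] == 0)

    def test_pair_separated_by_delay_shift_never_coincides(self):
        p = SynchronyParams()
        v1 = SpikeTrain([0.100], span=(0.0, 0.3))
        lgn = SpikeTrain([0.100], span=(0.0, 0.3))  # shifted to 105 ms
        _, raw = coincidence_series(v1, lgn, p)
        assert np.all(raw == 0)

    def test_count_product_inside_one_window(self):
        p = SynchronyParams()
        v1 = SpikeTrain([0.0995, 0.1005], span=(0.0, 0.3))
        lgn = SpikeTrain([0.0945, 0.0950, 0.0955], span=(0.0, 0.3))
        times, raw = coincidence_series(v1, lgn, p)
        assert raw.max() == 6  # 2 x 3
        assert raw[np.argmin(np.abs(times - 0.100))] == 6

    def test_matches_pair_enumeration_oracle(self, rng):
        p = SynchronyParams()
        for _ in range(12):
            v1 = poisson_train(rng, 40, 2.0, "V1")
            lgn = poisson_train(rng, 40, 2.0, "dLGN")
            times, raw = coincidence_series(v1, lgn, p)
            oracle = brute_force_coincidences(v1.times, lgn.times, times, p)
            assert np.array_equal(raw, oracle)

    def test_empty_train_warns_and_zeroes(self):
        v1 = SpikeTrain([], span=(0.0, 1.0))
        lgn = SpikeTrain([0.5], span=(0.0, 1.0))
        with pytest.warns(UserWarning, match="empty"):
            _, raw = coincidence_series(v1, lgn, SynchronyParams())
        assert np.all(raw == 0)


class TestJitter:
    def test_offsets_exclude_sub_minimum_displacements(self):
        offs = SynchronyParams().jitter_offsets_s() * 1000
        assert np.min(np.abs(offs)) == pytest.approx(2.0)
        assert np.max(np.abs(offs)) == pytest.approx(10.0)
        assert len(offs) == 34  # +-{2.0, 2.5, ..., 10.0}
        steps = np.unique(np.round(np.diff(np.sort(np.abs(offs))), 9))
        assert set(steps) <= {0.0, 0.5}

    def test_jitter_preserves_spike_count(self, rng):
        t = np.sort(rng.uniform(0, 10, 500))
        offs = SynchronyParams().jitter_offsets_s()
        for _ in range(5):
            assert jitter_spikes(t, offs, rng).size == t.size

    def test_jitter_preserves_coarse_rate(self, rng):
        t = np.sort(rng.uniform(0, 20, 2000))
        offs = SynchronyParams().jitter_offsets_s()
        edges = np.arange(0, 20.001, 0.025)
        orig, _ = np.histogram(t, edges)
        jit, _ = np.histogram(jitter_spikes(t, offs, rng), edges)
        # each spike moves at most 10 ms, so 25 ms counts move by neighbors
        assert np.abs(orig - jit).max() <= np.ceil(3 * np.sqrt(orig.max()))

    def test_invalid_jitter_window_combination_rejected(self):
        with pytest.raises(Exception):
            SynchronyParams(window_ms=4.5, jitter_max_ms=4.0)


class TestJitterCorrect:
    def test_independent_poisson_corrected_mean_near_zero(self, rng):
        p = SynchronyParams()
        v1 = poisson_train(rng, 25, 60.0, "V1")
        lgn = poisson_train(rng, 25, 60.0, "dLGN")
        sync = synchrony_series(v1, lgn, p, rng=rng)
        batch = sync.corrected[:118000].reshape(59, 2000).mean(axis=1)
        se = batch.std(ddof=1) / np.sqrt(batch.size)
        assert abs(sync.corrected.mean()) < 3 * se

    def test_exact_alignment_survives_correction(self):
        p = SynchronyParams(n_surrogates=100)
        v1 = SpikeTrain([0.100], span=(0.0, 0.3))
        lgn = SpikeTrain([0.095], span=(0.0, 0.3))
        times, raw = coincidence_series(v1, lgn, p)
        sync = jitter_correct(times, raw, v1, lgn, p, rng=0)
        i = np.argmin(np.abs(times - 0.100))
        assert sync.corrected_unsmoothed[i] > 0.5

    def test_rate_doubling_scales_raw_not_corrected(self, rng):
        p = SynchronyParams()
        v1a = poisson_train(rng, 15, 50.0, "V1")
        lgna = poisson_train(rng, 15, 50.0, "dLGN")
        v1b = poisson_train(rng, 30, 50.0, "V1")
        lgnb = poisson_train(rng, 30, 50.0, "dLGN")
        _, raw_a = coincidence_series(v1a, lgna, p)
        _, raw_b = coincidence_series(v1b, lgnb, p)
        assert raw_b.mean() / raw_a.mean() == pytest.approx(4.0, rel=0.35)
        sync_b = synchrony_series(v1b, lgnb, p, rng=rng)
        batch = sync_b.corrected[:98000].reshape(49, 2000).mean(axis=1)
        se = batch.std(ddof=1) / np.sqrt(batch.size)
        assert abs(sync_b.corrected.mean()) < 3 * se

    def test_corrected_equals_raw_minus_mean_before_smoothing(self, rng):
        p = SynchronyParams(n_surrogates=30)
        v1 = poisson_train(rng, 20, 10.0, "V1")
        lgn = poisson_train(rng, 20, 10.0, "dLGN")
        times, raw = coincidence_series(v1, lgn, p)
        sync = jitter_correct(times, raw, v1, lgn, p, rng=1)
        assert np.allclose(sync.corrected_unsmoothed,
                           sync.raw - sync.surrogate_mean)
        assert np.all(sync.raw >= 0)

    def test_translation_invariance_of_corrected_mean(self, rng):
        p = SynchronyParams(n_surrogates=60)
        v1 = poisson_train(rng, 20, 30.0, "V1")
        lgn = poisson_train(rng, 20, 30.0, "dLGN")
        s0 = synchrony_series(v1, lgn, p, rng=7)
        s1 = synchrony_series(v1.shifted(3.0), lgn.shifted(3.0), p, rng=7)
        assert s1.corrected.mean() == pytest.approx(s0.corrected.mean(),
                                                    abs=0.003)

    def test_locking_strength_recovery_is_monotone(self):
        # programmed increase of locking_kappa raises post-stimulus synchrony
        kappas = [0.0, 0.75, 1.5, 2.5, 4.0]
        scores = []
        for kappa in kappas:
            sc = CouplingScenario(duration_s=30.0, n_trials=8,
                                  locking_kappa=kappa, seed=77)
            ses = generate_session(sc)
            sync = synchrony_series(pool_trains(ses.spikes_v1),
                                    pool_trains(ses.spikes_lgn), rng=5)
            wave = event_triggered_synchrony(sync, ses.events,
                                             window=(0.1, 0.4))
            scores.append(np.mean(wave.mean[wave.latencies > 0]))
        rho = spearmanr(kappas, scores).statistic
        assert rho > 0.9


class TestSmoothingAndAveraging:
    def test_boxcar_preserves_constant_including_edges(self):
        assert np.allclose(boxcar_smooth(np.full(50, 3.3), 9), 3.3)

    def test_constant_series_gives_constant_waveform(self, rng):
        p = SynchronyParams(n_surrogates=25)
        v1 = poisson_train(rng, 20, 20.0, "V1")
        lgn = poisson_train(rng, 20, 20.0, "dLGN")
        sync = synchrony_series(v1, lgn, p, rng=2)
        sync.corrected[:] = 1.25
        wave = event_triggered_synchrony(
            sync, EventTable.from_arrays([5.0, 9.0, 14.0]),
            window=(0.25, 0.5))
        assert np.allclose(wave.mean, 1.25)
        assert wave.n_events == 3

    def test_events_beyond_series_are_dropped(self, rng):
        p = SynchronyParams(n_surrogates=25)
        v1 = poisson_train(rng, 20, 20.0, "V1")
        lgn = poisson_train(rng, 20, 20.0, "dLGN")
        sync = synchrony_series(v1, lgn, p, rng=3)
        wave = event_triggered_synchrony(
            sync, EventTable.from_arrays([5.0, 19.9]), window=(0.25, 0.5))
        assert wave.n_events == 1
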