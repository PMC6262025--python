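"""Condition splitting and synchrony-LFP correlation machinery."""

import numpy as np
import pytest

from gammasync import (EventTable, ParameterError, SynchronyParams,
                       band_monte_carlo_test, design_filter_bank,
                       analytic_decompose, lagged_pearson,
                       split_by_condition, xcorr_synchrony_lfp)
from gammasync.spikesync import SynchronySeries
import gammasync.synccorr as synccorr_mod
from .conftest import poisson_train


def lagged_pearson_oracle(x, y, mask, max_lag):
    """Direct per-lag Pearson over valid pairs (independent of the FFT
    implementation)."""
    n = x.size
    out = []
    for lag in range(-max_lag, max_lag + 1):
        t = np.arange(max(0, -lag), min(n, n - lag))
        ok = mask[t] & mask[t + lag]
        xs, ys = x[t][ok], y[t + lag][ok]
        if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
            out.append(np.nan)
        else:
            out.append(np.corrcoef(xs, ys)[0, 1])
    return np.array(out)


class TestSplitByCondition:
    def test_single_event_partition(self):
        ev = EventTable.from_arrays([10.0])
        gray, checker = split_by_condition(ev, (0.0, 20.0), response_s=0.5,
                                           guard_s=0.5)
        assert checker.intervals == [(10.0, 10.5)]
        assert gray.intervals == [(0.0, 10.0), (11.0, 20.0)]

    def test_no_events_all_gray(self):
        ev = EventTable.from_arrays([])
        gray, checker = split_by_condition(ev, (0.0, 20.0))
        assert checker.intervals == []
        assert gray.intervals == [(0.0, 20.0)]

    def test_total_checkerboard_time_bookkeeping(self):
        onsets = np.arange(5.0, 95.0, 3.0)
        gray, checker = split_by_condition(EventTable.from_arrays(onsets),
                                           (0.0, 100.0), response_s=0.5)
        assert checker.total_s() == pytest.approx(0.5 * onsets.size)
        assert gray.total_s() == pytest.approx(
            100.0 - onsets.size * (0.5 + 0.5))

    def test_overlapping_responses_merged_with_warning(self):
        ev = EventTable.from_arrays([10.0, 10.3])
        with pytest.warns(UserWarning, match="merged"):
            _, checker = split_by_condition(ev, (0.0, 20.0), response_s=0.5)
        assert checker.intervals == [(10.0, 10.8)]


class TestLaggedPearson:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_oracle_with_mask(self, seed):
        rng = np.random.default_rng(seed)
        n = 700
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        mask = np.ones(n, dtype=bool)
        mask[200:320] = False  # segment boundary in the middle
        got = lagged_pearson(x, y, mask, 25)
        want = lagged_pearson_oracle(x, y, mask, 25)
        assert np.allclose(got, want, atol=1e-10, equal_nan=True)

    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = rng.standard_normal(500)
        r = lagged_pearson(x, x, np.ones(500, bool), 10)
        assert r[10] == pytest.approx(1.0)

    def test_sign_flip_negates_all_lags(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        m = np.ones(500, bool)
        assert np.allclose(lagged_pearson(x, -y, m, 20),
                           -lagged_pearson(x, y, m, 20), atol=1e-10)


def _sync_from(times, corrected, params=None):
    z = np.zeros_like(corrected)
    return SynchronySeries(times=times, raw=np.abs(corrected), corrected=corrected,
                           corrected_unsmoothed=corrected, surrogate_mean=z,
                           surrogate_sd=z, params=params or SynchronyParams())


class TestXcorrSynchronyLfp:
    def test_band_self_correlation_peaks_at_one(self):
        from gammasync import LfpSignal

        rng = np.random.default_rng(3)
        fs = 2000.0
        sig = LfpSignal(rng.standard_normal(int(30 * fs)), fs=fs)
        bank = design_filter_bank(fs, 58, 62)
        dec = analytic_decompose(sig, bank)
        i = dec.index_of(60.0)
        times = np.arange(int(30 * fs)) / fs
        sync = _sync_from(times, dec.band_signal(i).astype(float))
        seg = synccorr_mod.ConditionSegments("gray", [(1.0, 29.0)])
        xc = xcorr_synchrony_lfp(sync, dec, seg, max_lag_ms=10.0)
        zero = np.argmin(np.abs(xc.lags_ms))
        assert xc.r[i, zero] == pytest.approx(1.0, abs=1e-6)
        assert np.nanmax(np.abs(xc.r)) <= 1.0 + 1e-9

    def test_empty_segments_rejected(self, rng):
        times = np.arange(2000) / 2000.0
        sync = _sync_from(times, rng.standard_normal(2000))
        seg = synccorr_mod.ConditionSegments("checkerboard", [])
        with pytest.raises(ParameterError):
            xcorr_synchrony_lfp(sync, None, seg)


class TestBandMonteCarlo:
    def test_identity_jitter_makes_observed_equal_median(self, rng,
                                                         monkeypatch):
        # degenerate surrogate: no displacement -> every surrogate equals the
        # observed series, so the median-subtracted curve is exactly zero
        from gammasync import LfpSignal

        monkeypatch.setattr(synccorr_mod, "jitter_spikes",
                            lambda t, offs, rng_: np.sort(t))
        fs = 2000.0
        lfp = LfpSignal(rng.standard_normal(int(30 * fs)), fs=fs)
        v1 = poisson_train(rng, 20, 30.0, "V1")
        lgn = poisson_train(rng, 20, 30.0, "dLGN")
        seg = synccorr_mod.ConditionSegments("gray", [(0.5, 29.5)])
        res = band_monte_carlo_test(lfp, v1, lgn, seg,
                                    n_surrogates=100, rng=1)
        assert np.allclose(res.observed, 0.0, atol=1e-12)
        assert res.n_significant == 0

    def test_deterministic_given_rng_seed(self, rng):
        from gammasync import LfpSignal

        fs = 2000.0
        x = rng.standard_normal(int(25 * fs))
        lfp = LfpSignal(x, fs=fs)
        v1 = poisson_train(rng, 25, 25.0, "V1")
        lgn = poisson_train(rng, 25, 25.0, "dLGN")
        seg = synccorr_mod.ConditionSegments("gray", [(0.5, 24.5)])
        a = band_monte_carlo_test(lfp, v1, lgn, seg, n_surrogates=120, rng=9)
        b = band_monte_carlo_test(lfp, v1, lgn, seg, n_surrogates=120, rng=9)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.threshold_hi, b.threshold_hi)

    def test_locked_session_shows_alternating_peaks_and_troughs(
            self, locked68_session):
        ses, v1, lgn, sync = locked68_session
        span = (0.0, ses.truth.duration_s)
        _, checker = split_by_condition(ses.events, span)
        res = band_monte_carlo_test(ses.lfp_v1, v1, lgn, checker,
                                    n_surrogates=200, rng=3, sync=sync)
        assert res.significant_pos.sum() >= 1
        assert res.significant_neg.sum() >= 1
        # oscillatory signature: peak spacing near the locking period
        pk = res.lags_ms[np.flatnonzero(
            (res.observed > np.roll(res.observed, 1))
            & (res.observed > np.roll(res.observed, -1))
            & res.significant_pos)]
        if pk.size >= 2:
            spacing = np.median(np.diff(pk))
            assert spacing == pytest.approx(1000.0 / 68.0, rel=0.25)
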