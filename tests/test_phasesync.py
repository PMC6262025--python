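"""Pairwise phase consistency and the PPC-amplitude surrogate test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import i0, i1

from gammasync import (CouplingScenario, ParameterError, TimeFrequencyMap,
                       analytic_decompose, design_filter_bank,
                       fisher_average, generate_session, ppc,
                       ppc_amplitude_correlation, time_resolved_ppc)


def ppc_pairwise_oracle(phases):
    """Brute-force mean of cos(theta_j - theta_k) over distinct pairs."""
    ph = np.asarray(phases, dtype=float)
    d = np.cos(ph[:, None] - ph[None, :])
    n = ph.size
    iu = np.triu_indices(n, k=1)
    return d[iu].mean()


class TestPpc:
    def test_identical_phases_give_one(self):
        assert ppc(np.full(17, 1.3)) == pytest.approx(1.0)

    def test_symmetric_four_point_set(self):
        assert ppc([0, np.pi / 2, np.pi, 3 * np.pi / 2]) == pytest.approx(
            -1 / 3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=40))
    def test_matches_pairwise_oracle(self, phases):
        assert ppc(phases) == pytest.approx(ppc_pairwise_oracle(phases),
                                            abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=25),
           st.floats(-10, 10))
    def test_invariant_to_common_phase_offset(self, phases, c):
        shifted = np.asarray(phases) + c
        assert ppc(shifted) == pytest.approx(ppc(phases), abs=1e-9)

    def test_von_mises_population_value(self, rng):
        # population PPC of von Mises(kappa) is (I1/I0)^2 -- Bessel oracle
        draws = rng.vonmises(0.0, 2.0, size=10_000)
        expected = (i1(2.0) / i0(2.0)) ** 2
        assert ppc(draws) == pytest.approx(expected, abs=0.01)

    def test_uniform_phases_unbiased_near_zero(self, rng):
        # contrast: the squared resultant R^2/N^2 is biased up by 1/N
        vals = [ppc(rng.uniform(-np.pi, np.pi, 20)) for _ in range(400)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_lower_bound_is_minus_one_over_n_minus_one(self):
        n = 4
        assert ppc(2 * np.pi * np.arange(n) / n) >= -1 / (n - 1) - 1e-12

    def test_too_few_phases_raises(self):
        with pytest.raises(ParameterError):
            ppc([0.0])


class TestFisherAverage:
    def test_identical_inputs_fixed_point(self):
        assert fisher_average([0.5, 0.5]) == pytest.approx(0.5)

    def test_differs_from_arithmetic_mean(self):
        # direct evaluation oracle: tanh(atanh(0.8)/2) = 0.5 exactly
        expected = np.tanh(np.arctanh(0.8) / 2)
        got = fisher_average([0.0, 0.8])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got != pytest.approx(0.4, abs=1e-3)

    def test_odd_symmetry(self):
        assert fisher_average([0.7, -0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_unit_coefficient_rejected(self):
        with pytest.raises(ParameterError):
            fisher_average([0.3, 1.0])


@pytest.fixture(scope="module")
def shared_and_null_maps():
    out = {}
    for name, coupling in (("shared", 1.0), ("null", 0.0)):
        sc = CouplingScenario(duration_s=40.0, n_trials=10,
                              coupling=coupling, locking_kappa=0.0,
                              burst_gain=1.0, evoked_lock=0.0, seed=42)
        ses = generate_session(sc)
        bank = design_filter_bank(2000.0, 55, 65)
        dv = analytic_decompose(ses.lfp_v1, bank)
        dl = analytic_decompose(ses.lfp_lgn, bank)
        out[name] = time_resolved_ppc(dv, dl, ses.events,
                                      window=(0.25, 0.0))
    return out


class TestTimeResolvedPpc:
    def test_shared_source_high_ppc_at_center(self, shared_and_null_maps):
        m = shared_and_null_maps["shared"]
        assert np.mean(m.row(60.0)) > 0.5

    def test_independent_sources_ppc_near_zero(self, shared_and_null_maps):
        m = shared_and_null_maps["null"]
        n = m.meta["n_trials"]
        # null PPC spread ~ sqrt(2/(N(N-1))) per point
        assert abs(np.mean(m.row(60.0))) < 0.15
        assert np.min(m.values) >= -1 / (n - 1) - 1e-9

    def test_shared_exceeds_null_clearly(self, shared_and_null_maps):
        assert (np.mean(shared_and_null_maps["shared"].row(60.0))
                > np.mean(shared_and_null_maps["null"].row(60.0)) + 0.3)


class TestPpcAmplitudeCorrelation:
    def _maps(self, values_ppc, values_amp, dt=0.001):
        n_f, n_t = values_ppc.shape
        freqs = 50.0 + np.arange(n_f)
        times = -0.25 + dt * np.arange(n_t)
        return (TimeFrequencyMap(freqs, times, values_ppc, "ppc"),
                TimeFrequencyMap(freqs, times, values_amp,
                                 "percent_amplitude_change"))

    def test_affine_relation_gives_r_one_and_positive_flag(self, rng):
        x = rng.standard_normal((3, 600)) * 0.1 + 0.3
        ppc_map, amp_map = self._maps(x, 7.0 * x + 2.0)
        res = ppc_amplitude_correlation(ppc_map, amp_map, n_surrogates=500,
                                        rng=0)
        assert np.allclose(res.r, 1.0)
        assert res.significant_pos.all()
        assert res.r_squared_at_peak == pytest.approx(1.0)

    def test_sign_flip_gives_negative_flag(self, rng):
        x = rng.standard_normal((2, 600)) * 0.1 + 0.3
        ppc_map, amp_map = self._maps(x, -3.0 * x)
        res = ppc_amplitude_correlation(ppc_map, amp_map, n_surrogates=500,
                                        rng=0)
        assert np.allclose(res.r, -1.0)
        assert res.significant_neg.all()

    def test_constant_series_flagged_nan_not_significant(self, rng):
        x = rng.standard_normal((2, 600))
        x[1] = 0.25  # constant PPC row -> undefined r
        ppc_map, amp_map = self._maps(x, rng.standard_normal((2, 600)))
        res = ppc_amplitude_correlation(ppc_map, amp_map, n_surrogates=200,
                                        rng=0)
        assert np.isnan(res.r[1])
        assert not res.significant_pos[1] and not res.significant_neg[1]

    def test_surrogate_r_equals_shifted_pearson(self, rng):
        # the FFT circular-xcorr shortcut must equal literal roll-then-corr
        x = rng.standard_normal(600)
        y = rng.standard_normal(600) + np.sin(np.arange(600) / 40)
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        xc = np.fft.irfft(np.conj(np.fft.rfft(zx)) * np.fft.rfft(zy),
                          600) / 600
        for s in (73, 250, 401):
            literal = np.corrcoef(np.roll(x, s), y)[0, 1]
            assert xc[s] == pytest.approx(literal, abs=1e-10)

    def test_grid_mismatch_rejected(self, rng):
        ppc_map, amp_map = self._maps(rng.random((2, 600)),
                                      rng.random((2, 600)))
        amp_map.freqs = amp_map.freqs + 1.0
        with pytest.raises(ParameterError):
            ppc_amplitude_correlation(ppc_map, amp_map, n_surrogates=100)
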