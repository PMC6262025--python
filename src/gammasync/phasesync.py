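"""Time-resolved pairwise phase consistency (PPC) between dLGN and V1.

PPC is the unbiased average cosine of all pairwise phase differences across
observations,

    PPC = (|sum_j exp(i theta_j)|^2 - N) / (N (N - 1)),

which equals the mean of cos(theta_j - theta_k) over the N(N-1)/2 distinct
pairs and, unlike the squared resultant, has expectation 0 for uniform
phases at any N.  Here the observations are across-trial phase differences
``theta_V1 - theta_dLGN`` at a fixed frequency and stimulus latency.

The PPC-amplitude test correlates, per frequency, the PPC time course with
the trial-mean amplitude time course over peri-stimulus latencies, and
calibrates significance with circular-shift surrogates: the PPC series is
rotated in time by a random guarded offset and the correlation recomputed
(2000 surrogates by default; pointwise 5th/95th percentile thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventTable, ParameterError, TimeFrequencyMap
from .spectral import AnalyticSeries, _event_sample_grid


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency of a sample of phases (radians).

    Range ``[-1/(N-1), 1]``; expectation 0 under uniform phases.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ParameterError("PPC needs at least two phases")
    if not np.all(np.isfinite(phases)):
        raise ParameterError("PPC input contains non-finite phases")
    s = np.exp(1j * phases).sum()
    return float((np.abs(s) ** 2 - n) / (n * (n - 1)))


@dataclass
class PhasePairSet:
    """Across-trial phase differences on a (frequency, latency) grid.

    ``delta_phases`` has shape ``(n_trials, n_freqs, n_latencies)`` with
    values wrapped to (-pi, pi].
    """

    delta_phases: np.ndarray
    freqs: np.ndarray
    latencies: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.delta_phases.shape[0]


def collect_phase_pairs(v1: AnalyticSeries, lgn: AnalyticSeries,
                        events: EventTable,
                        window: tuple[float, float] = (0.25, 0.5),
                        step_ms: float = 1.0) -> PhasePairSet:
    """Gather ``theta_V1 - theta_dLGN`` per trial on a 1 ms latency grid."""
    if v1.fs != lgn.fs or not np.array_equal(v1.freqs, lgn.freqs):
        raise ParameterError(
            "V1 and dLGN series must share sampling rate and filter bank")
    pre_s, post_s = window
    lat, _, onset_idx, _ = _event_sample_grid(
        v1, events, pre_s, post_s, baseline_s=0.0, step_ms=step_ms)
    if onset_idx.size < 2:
        raise ParameterError("need at least two usable events for PPC")
    idx = onset_idx[:, None] + lat[None, :]
    n_trials, n_lat = idx.shape
    nb = v1.freqs.size
    delta = np.empty((n_trials, nb, n_lat), dtype=np.float32)
    for i in range(nb):
        d = v1.phase[i][idx].astype(np.float64) - lgn.phase[i][idx]
        delta[:, i, :] = np.angle(np.exp(1j * d))
    return PhasePairSet(delta_phases=delta, freqs=v1.freqs.copy(),
                        latencies=lat / v1.fs)


def time_resolved_ppc(v1: AnalyticSeries, lgn: AnalyticSeries,
                      events: EventTable,
                      window: tuple[float, float] = (0.25, 0.5),
                      step_ms: float = 1.0) -> TimeFrequencyMap:
    """PPC of the dLGN-V1 phase difference across trials, per frequency and
    1 ms latency.  The trial count is carried in ``meta['n_trials']``."""
    pairs = collect_phase_pairs(v1, lgn, events, window, step_ms)
    n = pairs.n_trials
    z = np.exp(1j * pairs.delta_phases.astype(np.float64))
    s = z.sum(axis=0)
    values = (np.abs(s) ** 2 - n) / (n * (n - 1))
    return TimeFrequencyMap(freqs=pairs.freqs, times=pairs.latencies,
                            values=values, kind="ppc",
                            meta={"n_trials": n})


@dataclass
class PpcAmplitudeResult:
    """Per-frequency PPC-amplitude correlation with surrogate thresholds."""

    freqs: np.ndarray
    r: np.ndarray
    threshold_lo: np.ndarray
    threshold_hi: np.ndarray
    significant_pos: np.ndarray
    significant_neg: np.ndarray
    n_surrogates: int
    peak_freq: float
    r_squared_at_peak: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "freq_hz": self.freqs,
            "r": self.r,
            "threshold_5th": self.threshold_lo,
            "threshold_95th": self.threshold_hi,
            "significant_pos": self.significant_pos,
            "significant_neg": self.significant_neg,
        })


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, ok


def ppc_amplitude_correlation(ppc_map: TimeFrequencyMap,
                              amp_map: TimeFrequencyMap,
                              n_surrogates: int = 2000,
                              guard_s: float = 0.05,
                              rng: np.random.Generator | int | None = None,
                              ) -> PpcAmplitudeResult:
    """Correlate PPC and mean-amplitude time courses per frequency and test
    against circular-shift surrogates.

    A circular shift leaves the mean and variance of the PPC series intact,
    so the surrogate Pearson r at shift s is exactly the circular
    cross-correlation of the z-scored series at lag s; it is computed by FFT
    once per frequency and sampled at ``n_surrogates`` random shifts at least
    ``guard_s`` away from zero (mod the series length).
    """
    if ppc_map.kind != "ppc" or amp_map.kind != "percent_amplitude_change":
        raise ParameterError(
            "expected maps of kind 'ppc' and 'percent_amplitude_change'")
    if not (np.array_equal(ppc_map.freqs, amp_map.freqs)
            and np.array_equal(ppc_map.times, amp_map.times)):
        raise ParameterError("maps must share frequency and latency grids")
    rng = np.random.default_rng(rng)
    n_t = ppc_map.times.size
    dt = float(np.median(np.diff(ppc_map.times)))
    guard = int(round(guard_s / dt))
    if not (0 < guard < n_t // 2):
        raise ParameterError(
            f"guard of {guard_s} s infeasible for a {n_t}-point series")

    zp, ok_p = _zscore_rows(ppc_map.values.astype(float))
    za, ok_a = _zscore_rows(amp_map.values.astype(float))
    ok = ok_p & ok_a

    r = np.sum(zp * za, axis=1) / n_t
    r[~ok] = np.nan

    # full circular xcorr per frequency, then sample guarded shifts
    fp = np.fft.rfft(zp, axis=1)
    fa = np.fft.rfft(za, axis=1)
    xc = np.fft.irfft(np.conj(fp) * fa, n=n_t, axis=1) / n_t
    shifts = rng.integers(guard, n_t - guard, size=n_surrogates)
    sur = xc[:, shifts]  # (n_freq, n_surrogates)
    lo = np.percentile(sur, 5, axis=1)
    hi = np.percentile(sur, 95, axis=1)
    lo[~ok] = np.nan
    hi[~ok] = np.nan
    sig_pos = ok & (r > hi)
    sig_neg = ok & (r < lo)

    # R^2 at the frequency of peak evoked amplitude (post-stimulus)
    post = amp_map.times >= 0
    peak_i = int(np.argmax(np.max(amp_map.values[:, post], axis=1)))
    r_at_peak = r[peak_i]
    return PpcAmplitudeResult(
        freqs=ppc_map.freqs.copy(), r=r, threshold_lo=lo, threshold_hi=hi,
        significant_pos=sig_pos, significant_neg=sig_neg,
        n_surrogates=n_surrogates, peak_freq=float(ppc_map.freqs[peak_i]),
        r_squared_at_peak=float(r_at_peak ** 2) if np.isfinite(r_at_peak)
        else float("nan"))


def fisher_average(r_values) -> float:
    """Average correlation coefficients via the Fisher z-transform:
    ``tanh(mean(atanh(r_i)))``."""
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise ParameterError("no coefficients to average")
    if np.any(np.abs(r) >= 1):
        raise ParameterError("|r| = 1 has an infinite Fisher transform")
    return float(np.tanh(np.mean(np.arctanh(r))))
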