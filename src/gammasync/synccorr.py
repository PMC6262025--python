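"""Correlation of spike synchrony with band-limited V1 LFP oscillations.

The corrected synchrony series is cross-correlated, per frequency band and
per lag, with the signed band-passed V1 LFP voltage, separately for gray and
checkerboard viewing.  Significance for the 50-90 Hz high-gamma band comes
from a Monte Carlo test: surrogate synchrony series are rebuilt from
dLGN-jittered spike trains (V1 spikes untouched) and the observed lag curve
is compared with pointwise 5th/95th surrogate percentiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EventTable, LfpSignal, ParameterError, SpikeTrain
from .spectral import AnalyticSeries
from .spikesync import (SynchronyParams, SynchronySeries, _window_counts,
                        boxcar_smooth, coincidence_series, jitter_correct,
                        jitter_spikes)

log = logging.getLogger(__name__)


@dataclass
class ConditionSegments:
    """Disjoint, sorted half-open time intervals of one viewing condition."""

    condition: str
    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.intervals
                    if b > a)
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ParameterError("condition intervals overlap")
        self.intervals = iv

    def total_s(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def mask(self, times: np.ndarray) -> np.ndarray:
        m = np.zeros(times.size, dtype=bool)
        for a, b in self.intervals:
            m |= (times >= a) & (times < b)
        return m


def split_by_condition(events: EventTable, span: tuple[float, float],
                       response_s: float = 0.5, guard_s: float = 0.5,
                       ) -> tuple[ConditionSegments, ConditionSegments]:
    """Split the recording span into checkerboard response epochs
    ``[onset, onset + response_s)`` and the remaining gray time, excluding a
    ``guard_s`` buffer after each response window from the gray segments.
    Overlapping response windows are merged with a warning.
    """
    lo, hi = span
    onsets = np.sort(events.select("checkerboard").onsets) if len(events) \
        else np.array([])
    onsets = onsets[(onsets >= lo) & (onsets < hi)]
    checker: list[tuple[float, float]] = []
    for t in onsets:
        a, b = t, min(t + response_s, hi)
        if checker and a < checker[-1][1]:
            warnings.warn("overlapping response windows merged", stacklevel=2)
            checker[-1] = (checker[-1][0], b)
        else:
            checker.append((a, b))
    gray: list[tuple[float, float]] = []
    cursor = lo
    for a, b in checker:
        if a > cursor:
            gray.append((cursor, a))
        cursor = max(cursor, b + guard_s)
    if cursor < hi:
        gray.append((cursor, hi))
    return (ConditionSegments("gray", gray),
            ConditionSegments("checkerboard", checker))


def lagged_pearson(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
                   max_lag: int) -> np.ndarray:
    """Pearson r between ``x(t)`` and ``y(t + lag)`` for lags in
    ``[-max_lag, max_lag]`` samples, restricted to sample pairs where both
    ``mask[t]`` and ``mask[t + lag]`` hold.

    All lagged sums are cross-correlations of masked series and are computed
    with FFTs; the result is exact (up to float rounding), not windowed.
    """
    pre = _LagCorrPlan(y, mask, max_lag)
    return pre.correlate(x)


class _LagCorrPlan:
    """Precomputed FFT factors of the fixed (y, mask) side of a lagged
    Pearson correlation, so many x series can be correlated cheaply."""

    def __init__(self, y: np.ndarray, mask: np.ndarray, max_lag: int):
        n = y.size
        if mask.size != n:
            raise ParameterError("mask length must match series length")
        self.n = n
        self.max_lag = int(max_lag)
        self.nfft = int(2 ** np.ceil(np.log2(n + self.max_lag + 1)))
        m = mask.astype(np.float64)
        ym = y * m
        self.m = m
        self.F_m = np.fft.rfft(m, self.nfft)
        self.F_ym = np.fft.rfft(ym, self.nfft)
        self.F_y2m = np.fft.rfft(ym * y, self.nfft)
        # lagged sums that only involve y and the mask
        self.S_n = self._xcorr(self.F_m, self.F_m)
        self.S_y = self._xcorr(self.F_m, self.F_ym)
        self.S_yy = self._xcorr(self.F_m, self.F_y2m)

    def _xcorr(self, F_a: np.ndarray, F_b: np.ndarray) -> np.ndarray:
        """sum_t a[t] b[t + lag] for lag in [-max_lag, max_lag]."""
        full = np.fft.irfft(np.conj(F_a) * F_b, self.nfft)
        L = self.max_lag
        return np.concatenate([full[-L:], full[:L + 1]]) if L else full[:1]

    def correlate(self, x: np.ndarray) -> np.ndarray:
        if x.size != self.n:
            raise ParameterError("series length mismatch")
        xm = x * self.m
        F_xm = np.fft.rfft(xm, self.nfft)
        F_x2m = np.fft.rfft(xm * x, self.nfft)
        S_xy = self._xcorr(F_xm, self.F_ym)
        S_x = self._xcorr(F_xm, self.F_m)
        S_xx = self._xcorr(F_x2m, self.F_m)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = self.S_n
            cov = S_xy - S_x * self.S_y / n
            vx = S_xx - S_x ** 2 / n
            vy = self.S_yy - self.S_y ** 2 / n
            r = cov / np.sqrt(vx * vy)
        r[(self.S_n < 2)] = np.nan
        return np.clip(r, -1.0, 1.0, out=r)


@dataclass
class SyncLfpCorrelation:
    """Frequency x lag correlation between synchrony and band-passed LFP."""

    freqs: np.ndarray
    lags_ms: np.ndarray
    r: np.ndarray
    condition: str
    n_samples: int


def _segment_mask_for(series_times: np.ndarray,
                      segments: ConditionSegments,
                      max_lag_samples: int, step_s: float) -> np.ndarray:
    mask = np.zeros(series_times.size, dtype=bool)
    n_dropped = 0
    for a, b in segments.intervals:
        if (b - a) < 2 * max_lag_samples * step_s:
            n_dropped += 1
            continue
        mask |= (series_times >= a) & (series_times < b)
    if n_dropped:
        log.info("dropped %d %s segments shorter than twice the lag range",
                 n_dropped, segments.condition)
    return mask


def _resample_to(times: np.ndarray, sig_t0: float, sig_fs: float,
                 sig: np.ndarray) -> np.ndarray:
    """Band signal sampled onto the synchrony grid (linear interpolation is
    exact when the grids coincide)."""
    src_t = sig_t0 + np.arange(sig.size) / sig_fs
    return np.interp(times, src_t, sig)


def xcorr_synchrony_lfp(sync: SynchronySeries, v1: AnalyticSeries,
                        segments: ConditionSegments,
                        max_lag_ms: float = 50.0) -> SyncLfpCorrelation:
    """Per-frequency, per-lag Pearson correlation between the corrected
    synchrony series and the signed band-passed V1 LFP voltage, restricted
    to the given condition's segments."""
    if not segments.intervals:
        raise ParameterError(f"no {segments.condition} segments")
    step_s = sync.params.step_ms / 1000.0
    max_lag = int(round(max_lag_ms / sync.params.step_ms))
    mask = _segment_mask_for(sync.times, segments, max_lag, step_s)
    if mask.sum() < 2 * max_lag + 2:
        raise ParameterError("too few usable samples in the segments")
    x = sync.corrected.astype(np.float64)
    lags_ms = np.arange(-max_lag, max_lag + 1) * sync.params.step_ms
    r = np.empty((v1.freqs.size, lags_ms.size))
    for i in range(v1.freqs.size):
        band = _resample_to(sync.times, v1.t0, v1.fs, v1.band_signal(i))
        r[i] = lagged_pearson(x, band, mask, max_lag)
    return SyncLfpCorrelation(freqs=v1.freqs.copy(), lags_ms=lags_ms, r=r,
                              condition=segments.condition,
                              n_samples=int(mask.sum()))


@dataclass
class BandTestResult:
    """Monte Carlo test of the synchrony-LFP correlation in one band.

    ``observed`` and the thresholds are reported with the per-lag surrogate
    median subtracted; the significance flags are identical either way.
    """

    band: tuple[float, float]
    lags_ms: np.ndarray
    observed: np.ndarray
    threshold_lo: np.ndarray
    threshold_hi: np.ndarray
    surrogate_median: np.ndarray
    significant_pos: np.ndarray
    significant_neg: np.ndarray
    n_surrogates: int
    condition: str

    @property
    def n_significant(self) -> int:
        return int(self.significant_pos.sum() + self.significant_neg.sum())


def bandpass_voltage(lfp: LfpSignal, band: tuple[float, float],
                     order_rule: int = 5) -> np.ndarray:
    """Zero-delay band-passed voltage: causal five-cycle FIR advanced by its
    group delay (same convention as the filter bank)."""
    fc = 0.5 * (band[0] + band[1])
    numtaps = int(round(order_rule * lfp.fs / fc))
    numtaps += 1 - numtaps % 2
    taps = sps.firwin(numtaps, list(band), pass_zero=False, window="hamming",
                      fs=lfp.fs)
    full = sps.fftconvolve(lfp.samples, taps, mode="full")
    gd = (numtaps - 1) // 2
    return full[gd:gd + lfp.n]


def band_monte_carlo_test(v1_lfp: LfpSignal, v1_spikes: SpikeTrain,
                          lgn_spikes: SpikeTrain,
                          segments: ConditionSegments,
                          band: tuple[float, float] = (50.0, 90.0),
                          params: SynchronyParams | None = None,
                          n_surrogates: int = 1000,
                          max_lag_ms: float = 50.0,
                          rng: np.random.Generator | int | None = None,
                          sync: SynchronySeries | None = None,
                          ) -> BandTestResult:
    """Monte Carlo significance test of the lag-resolved correlation between
    corrected spike synchrony and the band-passed V1 LFP.

    Each surrogate rebuilds the synchrony series after jittering every dLGN
    spike (+/-2-10 ms); V1 spikes are never touched.  Because the jitter
    preserves the coarse firing rate, the rate-correction term (the jitter
    surrogate mean of the observed series) is reused for every Monte Carlo
    surrogate rather than re-estimated with nested surrogates.
    Pointwise 5th/95th percentiles of the surrogate lag curves form the
    significance thresholds.
    """
    params = params or SynchronyParams()
    if band[0] <= 0 or band[1] >= v1_lfp.fs / 2:
        raise ParameterError("band outside the filterable range")
    if not segments.intervals:
        raise ParameterError(f"no {segments.condition} segments")
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates gives coarse percentile "
                      "thresholds", stacklevel=2)
    rng = np.random.default_rng(rng)
    if sync is None:
        times, raw = coincidence_series(v1_spikes, lgn_spikes, params)
        sync = jitter_correct(times, raw, v1_spikes, lgn_spikes, params, rng)
    times = sync.times
    step_s = params.step_ms / 1000.0
    max_lag = int(round(max_lag_ms / params.step_ms))
    mask = _segment_mask_for(times, segments, max_lag, step_s)
    if mask.sum() < 2 * max_lag + 2:
        raise ParameterError("too few usable samples in the segments")

    band_sig = _resample_to(times, v1_lfp.t0, v1_lfp.fs,
                            bandpass_voltage(v1_lfp, band))
    plan = _LagCorrPlan(band_sig, mask, max_lag)
    observed = plan.correlate(sync.corrected.astype(np.float64))

    half_w = params.window_ms / 2000.0
    delay = params.delay_ms / 1000.0
    offsets = params.jitter_offsets_s()
    width = max(1, int(round(params.smooth_ms / params.step_ms)))
    c_v1 = _window_counts(v1_spikes.times, times, half_w)
    lgn_shifted = lgn_spikes.times + delay
    sur = np.empty((n_surrogates, observed.size))
    for s in range(n_surrogates):
        jittered = jitter_spikes(lgn_shifted, offsets, rng)
        raw_s = c_v1 * _window_counts(jittered, times, half_w)
        corr_s = boxcar_smooth(raw_s - sync.surrogate_mean, width)
        sur[s] = plan.correlate(corr_s)
    lo = np.percentile(sur, 5, axis=0)
    hi = np.percentile(sur, 95, axis=0)
    med = np.median(sur, axis=0)
    sig_pos = observed > hi
    sig_neg = observed < lo
    lags_ms = np.arange(-max_lag, max_lag + 1) * params.step_ms
    return BandTestResult(band=band, lags_ms=lags_ms,
                          observed=observed - med,
                          threshold_lo=lo - med, threshold_hi=hi - med,
                          surrogate_median=med,
                          significant_pos=sig_pos, significant_neg=sig_neg,
                          n_surrogates=n_surrogates,
                          condition=segments.condition)
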