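"""Time-resolved, rate-corrected dLGN-V1 spike synchrony.

The raw synchrony statistic slides a short window (default 4.5 ms) along the
recording in 0.5 ms steps, after shifting dLGN spike times forward by the
thalamocortical conduction delay (default 5 ms), and takes the product of the
V1 and dLGN spike counts in the window.  Coincidences expected from firing
rate alone are estimated by jittering every dLGN spike by a uniform random
offset of +/-2-10 ms (0.5 ms resolution) -- destroying millisecond alignment
while preserving spike count and coarse rate -- and the mean over surrogate
data sets (default 200) is subtracted.  The corrected series is smoothed with
a 4.5 ms boxcar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EventTable, LfpSignal, ParameterError, SpikeTrain
from .spectral import (FilterBankSpec, analytic_decompose, design_filter_bank,
                       event_locked_amplitude_change)

log = logging.getLogger(__name__)


@dataclass
class SynchronyParams:
    """Parameters of the sliding-window coincidence statistic.

    delay_ms : conduction delay added to dLGN spike times (dLGN leads V1).
    window_ms : coincidence window width; counts use [t - w/2, t + w/2).
    step_ms : evaluation grid step.
    n_surrogates : jitter surrogates for the rate correction.
    jitter_min_ms/jitter_max_ms/jitter_res_ms : the per-spike offset is drawn
        uniformly from the two-sided set {+/-2.0, +/-2.5, ..., +/-10.0} ms.
    smooth_ms : boxcar width applied to the corrected series.
    """

    delay_ms: float = 5.0
    window_ms: float = 4.5
    step_ms: float = 0.5
    n_surrogates: int = 200
    jitter_min_ms: float = 2.0
    jitter_max_ms: float = 10.0
    jitter_res_ms: float = 0.5
    smooth_ms: float = 4.5

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ParameterError("coincidence window must be positive")
        if self.jitter_min_ms >= self.jitter_max_ms:
            raise ParameterError("jitter_min must be below jitter_max")
        if self.jitter_max_ms <= self.window_ms:
            raise ParameterError(
                "jitter_max must exceed the coincidence window, otherwise "
                "surrogates cannot destroy within-window alignment")
        if self.step_ms > self.window_ms:
            raise ParameterError("step must not exceed the window")
        if self.n_surrogates < 20:
            warnings.warn("fewer than 20 surrogates gives an unstable "
                          "correction mean", stacklevel=2)

    def jitter_offsets_s(self) -> np.ndarray:
        mags = np.arange(self.jitter_min_ms,
                         self.jitter_max_ms + self.jitter_res_ms / 2,
                         self.jitter_res_ms)
        return np.concatenate([-mags[::-1], mags]) / 1000.0


@dataclass
class SynchronySeries:
    """Raw and rate-corrected coincidence series on a uniform time grid.

    ``raw`` is the count product per window position (>= 0); ``corrected`` is
    ``raw - surrogate_mean`` after boxcar smoothing and may be negative.
    ``corrected_unsmoothed`` keeps the pointwise difference.
    """

    times: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray
    corrected_unsmoothed: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    params: SynchronyParams = field(default_factory=SynchronyParams)

    @property
    def fs(self) -> float:
        return 1000.0 / self.params.step_ms

    def as_lfp(self, region: str = "sync") -> LfpSignal:
        """View the corrected series as a uniformly sampled signal so the
        spectral machinery can be applied to it."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return LfpSignal(self.corrected, fs=self.fs,
                             t0=float(self.times[0]), region="V1")


def _window_counts(times: np.ndarray, grid: np.ndarray,
                   half_w: float) -> np.ndarray:
    """Spike counts in [t - w/2, t + w/2) for every grid point t."""
    lo = np.searchsorted(times, grid - half_w, side="left")
    hi = np.searchsorted(times, grid + half_w, side="left")
    return (hi - lo).astype(np.float64)


def _grid(span: tuple[float, float], step_s: float) -> np.ndarray:
    n = int(np.floor((span[1] - span[0]) / step_s)) + 1
    return span[0] + step_s * np.arange(n)


def coincidence_series(v1: SpikeTrain, lgn: SpikeTrain,
                       params: SynchronyParams | None = None,
                       span: tuple[float, float] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Raw coincidence series: product of V1 and delay-shifted dLGN spike
    counts in a sliding half-open window.  Returns ``(times, raw)``."""
    params = params or SynchronyParams()
    if span is None:
        lo = max(v1.span[0], lgn.span[0])
        hi = min(v1.span[1], lgn.span[1])
        if not np.isfinite(hi):
            all_t = np.concatenate([v1.times, lgn.times])
            hi = float(all_t.max()) if all_t.size else lo + 1.0
        span = (lo, hi)
    if span[1] <= span[0]:
        raise ParameterError("spike trains have no overlapping span")
    if v1.n == 0 or lgn.n == 0:
        warnings.warn("empty spike train; coincidence series is all zero",
                      stacklevel=2)
    grid = _grid(span, params.step_ms / 1000.0)
    half_w = params.window_ms / 2000.0
    c_v1 = _window_counts(v1.times, grid, half_w)
    c_lgn = _window_counts(lgn.times + params.delay_ms / 1000.0, grid, half_w)
    return grid, c_v1 * c_lgn


def boxcar_smooth(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centered boxcar; edges renormalized by the actual kernel overlap."""
    if width_samples <= 1:
        return x.copy()
    k = np.ones(width_samples)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def jitter_spikes(times: np.ndarray, offsets_s: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Displace every spike by an independent draw from ``offsets_s``;
    returns sorted times (spike count preserved by construction)."""
    return np.sort(times + rng.choice(offsets_s, size=times.size))


def jitter_correct(times: np.ndarray, raw: np.ndarray, v1: SpikeTrain,
                   lgn: SpikeTrain, params: SynchronyParams | None = None,
                   rng: np.random.Generator | int | None = None,
                   jitter_both: bool = False) -> SynchronySeries:
    """Subtract the mean coincidence series of dLGN-jittered surrogates.

    Only dLGN spikes are jittered by default (the conservative convention
    used throughout the statistics); ``jitter_both`` also jitters V1.
    """
    params = params or SynchronyParams()
    rng = np.random.default_rng(rng)
    offsets = params.jitter_offsets_s()
    half_w = params.window_ms / 2000.0
    delay = params.delay_ms / 1000.0
    lgn_shifted = lgn.times + delay
    c_v1 = _window_counts(v1.times, times, half_w)
    acc = np.zeros_like(raw)
    acc2 = np.zeros_like(raw)
    for _ in range(params.n_surrogates):
        lg = jitter_spikes(lgn_shifted, offsets, rng)
        if jitter_both:
            cv = _window_counts(jitter_spikes(v1.times, offsets, rng),
                                times, half_w)
        else:
            cv = c_v1
        s = cv * _window_counts(lg, times, half_w)
        acc += s
        acc2 += s * s
    mean = acc / params.n_surrogates
    var = np.maximum(acc2 / params.n_surrogates - mean ** 2, 0.0)
    corrected_unsmoothed = raw - mean
    width = max(1, int(round(params.smooth_ms / params.step_ms)))
    corrected = boxcar_smooth(corrected_unsmoothed, width)
    return SynchronySeries(times=times, raw=raw, corrected=corrected,
                           corrected_unsmoothed=corrected_unsmoothed,
                           surrogate_mean=mean, surrogate_sd=np.sqrt(var),
                           params=params)


def synchrony_series(v1: SpikeTrain, lgn: SpikeTrain,
                     params: SynchronyParams | None = None,
                     span: tuple[float, float] | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> SynchronySeries:
    """Convenience: raw coincidence series plus jitter correction."""
    params = params or SynchronyParams()
    times, raw = coincidence_series(v1, lgn, params, span)
    return jitter_correct(times, raw, v1, lgn, params, rng)


@dataclass
class SyncWaveform:
    """Event-triggered average of the corrected synchrony series."""

    latencies: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_events: int


def event_triggered_synchrony(series: SynchronySeries, events: EventTable,
                              window: tuple[float, float] = (0.25, 0.5),
                              ) -> SyncWaveform:
    """Average the corrected series across event-aligned windows."""
    pre_s, post_s = window
    step_s = series.params.step_ms / 1000.0
    lat = np.arange(int(round(-pre_s / step_s)),
                    int(round(post_s / step_s)) + 1)
    t0 = float(series.times[0])
    onset_idx = np.rint((events.onsets - t0) / step_s).astype(int)
    ok = (onset_idx + lat[0] >= 0) & (onset_idx + lat[-1] < series.times.size)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        log.info("dropped %d events outside the synchrony series", n_dropped)
    onset_idx = onset_idx[ok]
    if onset_idx.size == 0:
        raise ParameterError("no events fall inside the synchrony series")
    seg = series.corrected[onset_idx[:, None] + lat[None, :]]
    mean = seg.mean(axis=0)
    se = (seg.std(axis=0, ddof=1) / np.sqrt(seg.shape[0])
          if seg.shape[0] > 1 else np.full(lat.size, np.nan))
    return SyncWaveform(latencies=lat * step_s, mean=mean, se=se,
                        n_events=int(onset_idx.size))


def synchrony_spectrogram(series: SynchronySeries, events: EventTable,
                          bank: FilterBankSpec | None = None,
                          window: tuple[float, float] = (0.25, 0.5),
                          baseline_s: float = 0.25,
                          f_lo: float = 40.0, f_hi: float = 95.0):
    """Time-frequency map of the corrected synchrony series' rhythmicity.

    The corrected series is treated as a uniformly sampled signal, run
    through the standard analytic filter bank, and event-averaged with a
    pre-stimulus percent-change baseline.
    """
    sig = series.as_lfp()
    if bank is None:
        bank = design_filter_bank(sig.fs, f_lo, f_hi)
    dec = analytic_decompose(sig, bank)
    return event_locked_amplitude_change(dec, events, window=window,
                                         baseline_s=baseline_s)
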