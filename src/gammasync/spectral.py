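"""LFP time-frequency decomposition with a causal FIR filter bank.

Each LFP channel is split into narrow bands by windowed-sinc (Hamming) FIR
band-pass filters whose length equals five cycles of the band's center
frequency.  The analytic signal of each band (Hilbert transform) yields an
instantaneous amplitude envelope and phase per frequency.  Event-locked maps
express amplitude as a percent change from the mean over the second preceding
stimulus onset.

Group delay: the filters are causal, but by default each band's output is
advanced by its group delay so that response latencies are comparable across
bands; pass ``delay_compensated=False`` for strictly causal output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EventTable, LfpSignal, ParameterError, TimeFrequencyMap

log = logging.getLogger(__name__)

#: Number of carrier cycles spanned by each FIR filter.
DEFAULT_ORDER_RULE = 5

#: Center-frequency step (Hz) of auto-generated banks.
CENTER_STEP_HZ = 0.5

#: Per-band bandwidth range (Hz): narrowest at the lowest center, widest at
#: the highest, linearly interpolated in between.
BANDWIDTH_RANGE_HZ = (0.5, 5.0)


@dataclass
class FilterBankSpec:
    """Specification of a band-pass FIR filter bank.

    ``orders`` holds the five-cycle tap counts ``round(order_rule * fs / fc)``;
    the realised filters use ``numtaps`` (the next odd number when the rule
    gives an even count) so every band is a Type I FIR with integer group
    delay ``(numtaps - 1) / 2`` samples.
    """

    fs: float
    center_freqs: np.ndarray
    bandwidths: np.ndarray
    order_rule: int = DEFAULT_ORDER_RULE
    causal: bool = True
    delay_compensated: bool = True
    orders: np.ndarray = field(init=False)
    numtaps: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        if self.center_freqs.size == 0:
            raise ParameterError("filter bank has no center frequencies")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ParameterError("center frequencies must be ascending")
        if self.bandwidths.shape != self.center_freqs.shape:
            raise ParameterError("need one bandwidth per center frequency")
        lo_edge = self.center_freqs - self.bandwidths / 2
        hi_edge = self.center_freqs + self.bandwidths / 2
        if np.any(lo_edge <= 0):
            raise ParameterError("a band's lower edge reaches 0 Hz")
        if np.any(hi_edge >= self.fs / 2):
            raise ParameterError(
                f"a band's upper edge reaches the Nyquist rate {self.fs / 2} Hz")
        self.orders = np.rint(
            self.order_rule * self.fs / self.center_freqs).astype(int)
        if np.any(self.orders < 3):
            raise ParameterError("filter order below 3 samples")
        self.numtaps = np.where(self.orders % 2 == 0,
                                self.orders + 1, self.orders)

    @property
    def n_bands(self) -> int:
        return self.center_freqs.size

    def taps(self, i: int) -> np.ndarray:
        fc = self.center_freqs[i]
        bw = self.bandwidths[i]
        return sps.firwin(int(self.numtaps[i]),
                          [fc - bw / 2, fc + bw / 2],
                          pass_zero=False, window="hamming", fs=self.fs)

    def group_delay_samples(self, i: int) -> int:
        return (int(self.numtaps[i]) - 1) // 2


def design_filter_bank(fs: float, f_lo: float, f_hi: float,
                       order_rule: int = DEFAULT_ORDER_RULE,
                       step: float = CENTER_STEP_HZ,
                       causal: bool = True,
                       delay_compensated: bool = True) -> FilterBankSpec:
    """Design the standard bank: centers every 0.5 Hz from ``f_lo`` to
    ``f_hi``, bandwidth growing linearly from 0.5 Hz at the lowest center to
    5 Hz at the highest, tap count equal to five carrier cycles per band.
    """
    if not (0 < f_lo < f_hi):
        raise ParameterError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= fs / 2:
        raise ParameterError(
            f"f_hi={f_hi} Hz must stay below the Nyquist rate {fs / 2} Hz")
    n = int(round((f_hi - f_lo) / step)) + 1
    centers = f_lo + step * np.arange(n)
    bw_lo, bw_hi = BANDWIDTH_RANGE_HZ
    if n == 1:
        bandwidths = np.array([bw_lo])
    else:
        bandwidths = bw_lo + (bw_hi - bw_lo) * (centers - centers[0]) / (
            centers[-1] - centers[0])
    return FilterBankSpec(fs=fs, center_freqs=centers, bandwidths=bandwidths,
                          order_rule=order_rule, causal=causal,
                          delay_compensated=delay_compensated)


@dataclass
class AnalyticSeries:
    """Per-band amplitude envelope and instantaneous phase of one signal.

    ``amplitude`` and ``phase`` are ``(n_bands, n_samples)`` float32 arrays;
    phases lie in (-pi, pi].  ``n_edge`` gives, per band, the number of
    samples at each end contaminated by filter transients; event averaging
    excludes windows that touch them.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    fs: float
    t0: float
    bank: FilterBankSpec
    n_edge: np.ndarray
    region: str = ""

    @property
    def n_samples(self) -> int:
        return self.amplitude.shape[1]

    def band_signal(self, i: int) -> np.ndarray:
        """Reconstructed signed band-passed voltage ``A(t) cos(phi(t))``."""
        return self.amplitude[i] * np.cos(self.phase[i])

    def index_of(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq)))

    def edge_margin_s(self) -> float:
        """Widest transient margin across bands, in seconds."""
        return float(np.max(self.n_edge)) / self.fs


def analytic_decompose(lfp: LfpSignal, bank: FilterBankSpec) -> AnalyticSeries:
    """Band-pass each band of ``bank`` and take the analytic signal.

    Returns amplitude (|analytic|) and phase (angle of analytic) per band.
    With ``bank.delay_compensated`` the band outputs are advanced by their
    group delay so all bands share the input's time base.
    """
    if bank.fs != lfp.fs:
        raise ParameterError(
            f"bank designed for fs={bank.fs} Hz but signal has fs={lfp.fs} Hz")
    x = lfp.samples
    n = x.size
    nb = bank.n_bands
    amplitude = np.empty((nb, n), dtype=np.float32)
    phase = np.empty((nb, n), dtype=np.float32)
    n_edge = np.zeros(nb, dtype=int)
    for i in range(nb):
        taps = bank.taps(i)
        full = sps.fftconvolve(x, taps, mode="full")
        if bank.delay_compensated:
            gd = bank.group_delay_samples(i)
            y = full[gd:gd + n]
        else:
            y = full[:n]
        analytic = sps.hilbert(y)
        amplitude[i] = np.abs(analytic)
        phase[i] = np.angle(analytic)
        n_edge[i] = int(bank.numtaps[i])
    return AnalyticSeries(freqs=bank.center_freqs.copy(), amplitude=amplitude,
                          phase=phase, fs=lfp.fs, t0=lfp.t0, bank=bank,
                          n_edge=n_edge, region=lfp.region)


def notch_60hz(lfp: LfpSignal, q: float = 35.0) -> LfpSignal:
    """Plain 60 Hz IIR notch (zero-phase) for line-hum removal."""
    b, a = sps.iirnotch(60.0, q, fs=lfp.fs)
    return LfpSignal(sps.filtfilt(b, a, lfp.samples), fs=lfp.fs,
                     t0=lfp.t0, region=lfp.region)


def _event_sample_grid(series: AnalyticSeries, events: EventTable,
                       pre_s: float, post_s: float, baseline_s: float,
                       step_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Event-relative 1 ms (default) index grids, dropping events whose
    window or baseline leaves the transient-free part of the recording."""
    step_samp = max(1, int(round(series.fs * step_ms / 1000.0)))
    lat = np.arange(int(round(-pre_s * series.fs)),
                    int(round(post_s * series.fs)) + 1, step_samp)
    base_lat = np.arange(int(round(-baseline_s * series.fs)), 0, step_samp)
    margin = int(np.max(series.n_edge))
    onset_idx = np.rint((events.onsets - series.t0) * series.fs).astype(int)
    lo_need = min(lat[0], base_lat[0] if base_lat.size else 0)
    ok = ((onset_idx + lo_need >= margin)
          & (onset_idx + lat[-1] < series.n_samples - margin))
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        log.info("dropped %d events outside the usable recording span",
                 n_dropped)
    return lat, base_lat, onset_idx[ok], n_dropped


def event_locked_amplitude_change(series: AnalyticSeries, events: EventTable,
                                  window: tuple[float, float] = (1.0, 0.5),
                                  baseline_s: float = 1.0,
                                  step_ms: float = 1.0) -> TimeFrequencyMap:
    """Event-locked percent amplitude change from the pre-stimulus baseline.

    For each band the baseline is the mean envelope over ``[-baseline_s, 0)``
    pooled across events, and the map value is
    ``100 * (mean envelope(f, t) - baseline(f)) / baseline(f)`` on a grid of
    ``step_ms`` latencies spanning ``[-window[0], +window[1]]``.
    """
    if len(events) < 1:
        raise ParameterError("need at least one event")
    pre_s, post_s = window
    lat, base_lat, onset_idx, _ = _event_sample_grid(
        series, events, pre_s, post_s, baseline_s, step_ms)
    if onset_idx.size == 0:
        raise ParameterError("no events fit inside the recording")
    idx = onset_idx[:, None] + lat[None, :]
    bidx = onset_idx[:, None] + base_lat[None, :]
    nb = series.freqs.size
    values = np.empty((nb, lat.size))
    for i in range(nb):
        amp = series.amplitude[i]
        baseline = float(np.mean(amp[bidx]))
        if baseline == 0:
            raise ParameterError(
                f"zero baseline amplitude at {series.freqs[i]:.1f} Hz")
        values[i] = 100.0 * (np.mean(amp[idx], axis=0) - baseline) / baseline
    return TimeFrequencyMap(
        freqs=series.freqs.copy(), times=lat / series.fs, values=values,
        kind="percent_amplitude_change", baseline_window=(-baseline_s, 0.0),
        meta={"n_events": int(onset_idx.size), "region": series.region})
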