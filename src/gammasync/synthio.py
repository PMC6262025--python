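"""Synthetic paired dLGN-V1 sessions with known ground-truth coupling.

The generator emulates the phenomenology of awake mouse visual recordings:

* a 1/f^alpha background per region, independent between regions;
* a shared narrowband gamma source (default 60 Hz, 3 Hz bandwidth) present
  during gray-screen viewing, added to dLGN directly and to V1 after the
  thalamocortical conduction delay, with a ``coupling`` fraction of the V1
  copy shared with dLGN and the remainder an independent same-band source;
* contrast-evoked broadband 50-90 Hz oscillations during checkerboard
  trials whose envelope ramps to a peak ~112 ms after stimulus onset while
  the narrowband source is suppressed, plus a 25-35 Hz low-gamma component
  in V1 only;
* dLGN spiking as an inhomogeneous Poisson process locked to the dLGN gamma
  phase through a von Mises intensity (normalized by I0 so ``base_rate_hz``
  is the mean rate), with a burst-gain multiplier 30-80 ms after onset;
* V1 spiking as probabilistic relay of dLGN spikes (p_relay, conduction
  delay + 0.5 ms Gaussian timing jitter) plus an independent Poisson
  background.

``generate_null_session`` keeps the LFP construction but replaces both spike
trains with independent Poisson processes sharing a slow (<= 5 Hz) rate
envelope: coincidence rates co-fluctuate with rate, but no millisecond
synchrony exists.  This is the calibration fixture for the surrogate tests.

All stochastic draws come from one seeded generator in a fixed, documented
order (events, backgrounds, narrowband sources, broadband sources, low
gamma, dLGN units, V1 relay and background per unit), so a given scenario
and seed
reproduce a byte-identical session.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps
from scipy.special import i0

from .core import EventTable, LfpSignal, ParameterError, SpikeTrain

# Fixed phenomenology constants (amplitudes relative to a unit-SD background)
BACKGROUND_SD = 1.0
NARROWBAND_SD = 0.5
EVOKED_SD = 1.0
LOWGAMMA_SD = 0.45
BROADBAND_HZ = (50.0, 90.0)
LOWGAMMA_HZ = (25.0, 35.0)
RESPONSE_TAU_S = 0.1125       # alpha-function peak time -> 112.5 ms
RESPONSE_DUR_S = 0.6
EVOKED_PEAK_SD_HZ = 10.0      # spectral peak width of the evoked source
EVOKED_LOCK = 0.5             # stimulus phase-reset fraction of the source
BURST_WINDOW_S = (0.030, 0.080)
RESPONSE_RATE_GAIN = 3.0      # tonic contrast-driven rate gain at envelope peak
FIRST_ONSET_S = 2.0
RELAY_JITTER_SD_MS = 0.5


@dataclass
class CouplingScenario:
    """Ground-truth parameters of a synthetic session.

    ``coupling`` is the fraction of the V1 band-limited source shared with
    dLGN; ``locking_kappa`` the von Mises concentration of dLGN spikes on
    the gamma phase; ``conduction_delay_ms`` the lead of dLGN over V1.
    """

    duration_s: float = 900.0
    fs_lfp: float = 2000.0
    gamma_center: float = 60.0
    gamma_bandwidth: float = 3.0
    coupling: float = 0.8
    conduction_delay_ms: float = 5.0
    locking_kappa: float = 2.5
    base_rate_hz: float = 15.0
    burst_gain: float = 4.0
    n_trials: int = 250
    iti_range_s: tuple[float, float] = (2.5, 4.0)
    stim_duration_s: float = 0.1
    noise_exponent: float = 1.0
    seed: int = 0
    n_units: int = 1
    p_relay: float = 0.4
    evoked_lock: float = EVOKED_LOCK
    #: spectral peak of the contrast-evoked broadband source; the evoked
    #: high gamma sits higher in frequency than the gray-screen narrowband
    #: oscillation, so the default is gamma_center + 8 Hz
    evoked_peak_hz: float | None = None
    #: spectral width (Gaussian sigma, Hz) of the evoked source's peak;
    #: ~10 Hz reproduces the >20 Hz-wide contrast-evoked oscillation, small
    #: values give a sharp evoked rhythm at evoked_peak_hz
    evoked_peak_sd_hz: float = EVOKED_PEAK_SD_HZ

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError(f"coupling must lie in [0, 1], "
                                 f"got {self.coupling}")
        if self.gamma_center - self.gamma_bandwidth / 2 <= 0:
            raise ParameterError("gamma band's lower edge must be above 0 Hz")
        if not self.iti_range_s[0] < self.iti_range_s[1]:
            raise ParameterError("iti_range min must be below max")
        if self.fs_lfp < 2000:
            raise ParameterError(f"fs_lfp must be >= 2000 Hz, "
                                 f"got {self.fs_lfp}")
        for name in ("base_rate_hz", "stim_duration_s", "duration_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.locking_kappa < 0:
            raise ParameterError("locking_kappa must be >= 0")
        if self.burst_gain < 1:
            raise ParameterError("burst_gain must be >= 1")
        if not 0.0 <= self.p_relay <= 1.0:
            raise ParameterError("p_relay must lie in [0, 1]")
        if not 0.0 <= self.evoked_lock <= 1.0:
            raise ParameterError("evoked_lock must lie in [0, 1]")
        if self.evoked_peak_hz is None:
            self.evoked_peak_hz = self.gamma_center + 8.0
        if not (BROADBAND_HZ[0] <= self.evoked_peak_hz <= BROADBAND_HZ[1]):
            raise ParameterError(
                f"evoked_peak_hz must lie within {BROADBAND_HZ}")
        if self.evoked_peak_sd_hz <= 0:
            raise ParameterError("evoked_peak_sd_hz must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iti_range_s"] = list(self.iti_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingScenario":
        d = dict(d)
        if "iti_range_s" in d:
            d["iti_range_s"] = tuple(d["iti_range_s"])
        return cls(**d)


@dataclass
class SyntheticSession:
    """A generated session with its ground-truth scenario embedded."""

    lfp_v1: LfpSignal
    lfp_lgn: LfpSignal
    spikes_v1: list[SpikeTrain]
    spikes_lgn: list[SpikeTrain]
    events: EventTable
    truth: CouplingScenario
    #: ground-truth dLGN gamma phase used to lock spikes (float32, one value
    #: per LFP sample); None for null sessions, whose spikes are unlocked
    lgn_gamma_phase: "np.ndarray | None" = None


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  exponent: float) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-SD Gaussian noise strictly band-limited to ``band``.

    Synthesised by masking the spectrum of white noise, so the source truly
    has the stated bandwidth (a time-domain FIR of practical length would
    smear a few-Hz band over tens of Hz).
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _peaked_band_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float], peak_hz: float,
                       peak_sd_hz: float = EVOKED_PEAK_SD_HZ) -> np.ndarray:
    """Unit-SD noise with support on ``band`` and a Gaussian spectral peak.

    Models the evoked broadband gamma source: wide (> 20 Hz) support but a
    definite per-session peak frequency inside the band.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.exp(-0.5 * ((f - peak_hz) / peak_sd_hz) ** 2)
    w[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec * w, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _delayed(x: np.ndarray, d: int) -> np.ndarray:
    if d == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[d:] = x[:-d]
    return out


def _draw_events(rng: np.random.Generator, sc: CouplingScenario) -> np.ndarray:
    itis = rng.uniform(*sc.iti_range_s, size=sc.n_trials)
    onsets = FIRST_ONSET_S + np.concatenate([[0.0], np.cumsum(itis[:-1])])
    fit = onsets + RESPONSE_DUR_S + 1.0 < sc.duration_s
    return onsets[fit]


def _stim_envelope(n: int, fs: float, onsets: np.ndarray) -> np.ndarray:
    """Alpha-function envelope per trial, peak 1 at RESPONSE_TAU_S."""
    env = np.zeros(n)
    k = int(round(RESPONSE_DUR_S * fs))
    t = np.arange(k) / fs
    kernel = (t / RESPONSE_TAU_S) * np.exp(1.0 - t / RESPONSE_TAU_S)
    for onset in onsets:
        i = int(round(onset * fs))
        j = min(i + k, n)
        if i < n:
            env[i:j] = np.maximum(env[i:j], kernel[:j - i])
    return env


def _evoked_source(rng: np.random.Generator, sc: CouplingScenario, n: int,
                   fs: float, onsets: np.ndarray) -> np.ndarray:
    """Unit-SD carrier of the contrast-evoked broadband gamma.

    Broad 50-90 Hz support with a spectral peak at ``gamma_center``; a
    fraction ``EVOKED_LOCK`` of the carrier is a fixed per-session template
    replayed at every stimulus onset (emulating stimulus phase reset, which
    is what lets the rhythm survive trial averaging), the rest is ongoing
    band noise with random phase per trial.
    """
    k = int(round(RESPONSE_DUR_S * fs))
    template = _peaked_band_noise(rng, k, fs, BROADBAND_HZ,
                                  sc.evoked_peak_hz, sc.evoked_peak_sd_hz)
    ongoing = _peaked_band_noise(rng, n, fs, BROADBAND_HZ,
                                 sc.evoked_peak_hz, sc.evoked_peak_sd_hz)
    locked = np.zeros(n)
    for onset in onsets:
        i = int(round(onset * fs))
        j = min(i + k, n)
        if i < n:
            locked[i:j] = template[:j - i]
    w = sc.evoked_lock
    return w * locked + np.sqrt(1.0 - w * w) * ongoing


def _lfp_components(rng: np.random.Generator, sc: CouplingScenario,
                    n: int, onsets: np.ndarray):
    """LFP pieces in the documented draw order.  Returns the two LFP traces
    and the dLGN gamma drive (used to lock spikes)."""
    fs = sc.fs_lfp
    half_bw = sc.gamma_bandwidth / 2.0
    nb_band = (sc.gamma_center - half_bw, sc.gamma_center + half_bw)
    d = int(round(sc.conduction_delay_ms * fs / 1000.0))

    bg_v1 = _shaped_noise(rng, n, fs, sc.noise_exponent) * BACKGROUND_SD
    bg_lgn = _shaped_noise(rng, n, fs, sc.noise_exponent) * BACKGROUND_SD
    s = _band_noise(rng, n, fs, nb_band)
    s_ind = _band_noise(rng, n, fs, nb_band)
    b = _evoked_source(rng, sc, n, fs, onsets)
    b_ind = _evoked_source(rng, sc, n, fs, onsets)
    lowg = _band_noise(rng, n, fs, LOWGAMMA_HZ)

    env = _stim_envelope(n, fs, onsets)
    gate = 1.0 - env  # narrowband suppression during the evoked response
    c = sc.coupling

    gamma_lgn = gate * s * NARROWBAND_SD + env * b * EVOKED_SD
    v1_shared_src = (gate * (c * s + (1 - c) * s_ind) * NARROWBAND_SD
                     + env * (c * b + (1 - c) * b_ind) * EVOKED_SD)
    gamma_v1 = _delayed(v1_shared_src, d) + env * lowg * LOWGAMMA_SD

    lfp_v1 = bg_v1 + gamma_v1
    lfp_lgn = bg_lgn + gamma_lgn
    return lfp_v1, lfp_lgn, gamma_lgn


def _burst_factor(n: int, fs: float, onsets: np.ndarray,
                  gain: float) -> np.ndarray:
    """Burst-gain envelope: the 30-80 ms post-onset window with ~20 ms
    raised-cosine ramps (burst firing rises and falls over tens of ms; a
    step would put unphysical broadband splatter into the spike rate)."""
    ind = np.zeros(n)
    a, b = BURST_WINDOW_S
    for onset in onsets:
        i = int(round((onset + a) * fs))
        j = int(round((onset + b) * fs))
        ind[max(i, 0):min(j, n)] = 1.0
    k = int(round(0.020 * fs))
    if k > 1:
        win = np.hanning(k)
        ind = np.convolve(ind, win / win.sum(), mode="same")
    return 1.0 + (gain - 1.0) * ind


def _bernoulli_train(rng: np.random.Generator, p: np.ndarray,
                     fs: float) -> np.ndarray:
    """At most one spike per sample; p = rate * dt must stay below 1."""
    hits = np.flatnonzero(rng.random(p.size) < p)
    return hits / fs


def _finalize_train(times: np.ndarray, region: str, unit_id: str,
                    span: tuple[float, float]) -> SpikeTrain:
    times = np.sort(times)
    times = times[(times >= span[0]) & (times < span[1])]
    if times.size:
        keep = np.concatenate([[True], np.diff(times) >= 5e-5])
        times = times[keep]
    return SpikeTrain(times, region=region, unit_id=unit_id, span=span)


def generate_session(scenario: CouplingScenario) -> SyntheticSession:
    """Generate a coupled session; deterministic for a fixed seed."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs = sc.fs_lfp
    n = int(round(sc.duration_s * fs))
    span = (0.0, sc.duration_s)

    onsets = _draw_events(rng, sc)
    lfp_v1, lfp_lgn, gamma_lgn = _lfp_components(rng, sc, n, onsets)

    # dLGN: inhomogeneous Poisson locked to the dLGN gamma phase
    phase_lgn = np.angle(sps.hilbert(gamma_lgn))
    kappa = sc.locking_kappa
    mod = np.exp(kappa * np.cos(phase_lgn)) / i0(kappa)
    env = _stim_envelope(n, fs, onsets)
    tonic = 1.0 + (RESPONSE_RATE_GAIN - 1.0) * env
    rate_lgn = (sc.base_rate_hz * mod * tonic
                * _burst_factor(n, fs, onsets, sc.burst_gain))
    p_lgn = np.minimum(rate_lgn / fs, 0.9)
    spikes_lgn = [
        _finalize_train(_bernoulli_train(rng, p_lgn, fs),
                        "dLGN", f"lgn{u}", span)
        for u in range(sc.n_units)
    ]

    # V1: probabilistic relay of pooled dLGN spikes + Poisson background
    pooled_lgn = np.sort(np.concatenate([t.times for t in spikes_lgn]))
    delay_s = sc.conduction_delay_ms / 1000.0
    jitter_sd = RELAY_JITTER_SD_MS / 1000.0
    p_bg = np.full(n, sc.base_rate_hz / fs)
    spikes_v1 = []
    for u in range(sc.n_units):
        relayed = pooled_lgn[rng.random(pooled_lgn.size) < sc.p_relay]
        relayed = relayed + delay_s + rng.normal(0.0, jitter_sd,
                                                 relayed.size)
        background = _bernoulli_train(rng, p_bg, fs)
        spikes_v1.append(_finalize_train(
            np.concatenate([relayed, background]), "V1", f"v1_{u}", span))

    events = EventTable.from_arrays(onsets, "checkerboard",
                                    sc.stim_duration_s)
    return SyntheticSession(
        lfp_v1=LfpSignal(lfp_v1, fs=fs, region="V1"),
        lfp_lgn=LfpSignal(lfp_lgn, fs=fs, region="dLGN"),
        spikes_v1=spikes_v1, spikes_lgn=spikes_lgn,
        events=events, truth=sc,
        lgn_gamma_phase=phase_lgn.astype(np.float32))


def generate_null_session(scenario: CouplingScenario) -> SyntheticSession:
    """Null session: same LFP construction, but both regions' spikes are
    independent Poisson processes sharing a slow rate envelope.  Coincidence
    rates rise and fall together with the envelope, yet no fine-timescale
    synchrony exists -- the fixture for calibrating the surrogate tests."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs = sc.fs_lfp
    n = int(round(sc.duration_s * fs))
    span = (0.0, sc.duration_s)

    onsets = _draw_events(rng, sc)
    lfp_v1, lfp_lgn, _ = _lfp_components(rng, sc, n, onsets)

    # shared slow (<= 5 Hz) log-normal rate envelope, mean 1
    sos = sps.butter(4, 5.0, btype="low", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = z.std()
    z = z / sd if sd > 0 else z
    envelope = np.exp(0.5 * z - 0.125)

    p = np.minimum(sc.base_rate_hz * envelope / fs, 0.9)
    spikes_lgn = [
        _finalize_train(_bernoulli_train(rng, p, fs), "dLGN",
                        f"lgn{u}", span)
        for u in range(sc.n_units)
    ]
    spikes_v1 = [
        _finalize_train(_bernoulli_train(rng, p, fs), "V1",
                        f"v1_{u}", span)
        for u in range(sc.n_units)
    ]
    events = EventTable.from_arrays(onsets, "checkerboard",
                                    sc.stim_duration_s)
    return SyntheticSession(
        lfp_v1=LfpSignal(lfp_v1, fs=fs, region="V1"),
        lfp_lgn=LfpSignal(lfp_lgn, fs=fs, region="dLGN"),
        spikes_v1=spikes_v1, spikes_lgn=spikes_lgn,
        events=events, truth=sc)
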