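# Methods

`gammasync` analyses paired recordings from the dorsolateral geniculate
nucleus (dLGN) and primary visual cortex (V1) of awake mice viewing a gray
screen interrupted by brief full-contrast checkerboard images. The question
it operationalises: do visual responses in V1 ride on band-limited gamma
oscillations that are phase-synchronized with the thalamus, and do
millisecond-precise dLGN–V1 spike coincidences occur specifically at those
oscillation frequencies? Four stages address it: LFP time–frequency
decomposition, time-resolved pairwise phase consistency (PPC), a
rate-corrected spike-synchrony statistic, and Monte Carlo surrogate tests
linking the two.

## Spectral decomposition

Each LFP channel is split into narrow bands by causal windowed-sinc
(Hamming) FIR band-pass filters. Centers run in 0.5 Hz steps; per-band
bandwidth is interpolated linearly from 0.5 Hz at the lowest center to 5 Hz
at the highest; the tap count of each filter equals five cycles of its
center frequency, `round(5 · fs / fc)` (made odd so group delay is an
integer). The analytic signal (Hilbert transform) of each band gives an
instantaneous amplitude envelope and phase.

Two consequences of the five-cycle rule matter for interpretation:

* **Group delay.** The filters are causal with delay `(taps − 1)/2`
  samples. By default every band is advanced by its own group delay so
  response latencies are comparable across bands
  (`delay_compensated=False` restores strictly causal output). The first
  and last `taps` samples of each band are treated as transient-
  contaminated and events whose windows touch them are dropped (counted in
  the log).
* **Effective bandwidth.** A five-cycle Hamming FIR has a transition width
  of roughly `0.66 · fc`, far wider than the nominal 0.5–5 Hz passband, so
  the realized bands behave like constant-Q filters (≈ ±20 Hz at 60 Hz).
  Frequency attributions at gamma are therefore accurate to a few hertz at
  best, and phase-synchrony estimates at one center frequency mix in
  neighbouring content. This resolution limit is inherent to the filter
  rule, and the tests account for it.

Event-locked maps express the trial-mean envelope as a percent change from
the mean envelope in the second before stimulus onset, pooled across
trials, on a 1 ms latency grid.

A 60 Hz IIR notch (Q = 35, zero-phase) is available as plumbing for
line-hum removal; it is off by default since synthetic sessions contain no
hum.

## Pairwise phase consistency

For each frequency and each 1 ms peri-stimulus latency, the across-trial
phase offsets Δθ = θ_V1 − θ_dLGN are summarised by

    PPC = (|Σ_j e^{iθ_j}|² − N) / (N (N − 1)),

the unbiased mean of cos(θ_j − θ_k) over distinct trial pairs. Unlike the
squared resultant it has expectation 0 under uniform phases at any trial
count; its range is [−1/(N−1), 1]. The sign convention Δθ = θ_V1 − θ_dLGN
makes a positive circular-mean offset a V1 lag.

**PPC–amplitude correlation.** Per frequency, the Pearson correlation over
latencies between the PPC time course and the trial-mean amplitude time
course asks whether an oscillation's amplitude grows specifically when the
two regions synchronize. Significance uses circular-shift surrogates: the
PPC series is rotated by a random offset (at least 50 ms away from zero,
modulo the window length) and the correlation recomputed, 2000 times by
default; pointwise 5th/95th surrogate percentiles per frequency form the
thresholds. Because a circular shift leaves the series' mean and variance
intact, the surrogate correlation at shift s equals the circular
cross-correlation of the z-scored series at lag s; the implementation
computes the full circular cross-correlation once per frequency by FFT and
samples it at random guarded shifts — exact, and fast enough to afford
large surrogate counts.

**Window length is a validity condition, not a tuning knob.** The shift
surrogate only samples the null well when the window is long relative to
the structures being shifted. With a 0.75 s peri-stimulus window the
evoked amplitude bump (~0.3 s) leaves only ~2 effectively independent
shift positions, and calibration runs on sessions with no PPC–amplitude
relation measured per-tail false-positive rates near 11% instead of 5%.
With a (−0.75, +1.25) s window the measured rates fall to ~5–9% per tail
(mean ≈ 7% over 400 null sessions). The correlation and its test
therefore default to the 2 s window; display maps keep the conventional
(−0.25, +0.5) s span. Trial spacing of at least 2.5 s makes the wide
window usable without overlapping adjacent responses. A residual ~+2
point anticonservativeness remains even so: a 2 s window holds only ~6–8
effectively independent shifts of a 0.3 s response, so the surrogate
percentiles under-sample the null tails no matter how many surrogates are
drawn. Findings whose correlation barely clears the pointwise threshold
should not be over-read.

`fisher_average` pools correlation coefficients across sessions or animals
as `tanh(mean(atanh(r)))`.

## Rate-corrected spike synchrony

dLGN spike times are first shifted forward by the 5 ms thalamocortical
conduction delay. A window of 4.5 ms — the integration span within which
synchronous thalamic input summates most effectively in cortex — slides in
0.5 ms steps, and the raw synchrony at each position is the product of V1
and shifted-dLGN spike counts in the half-open window [t − w/2, t + w/2).

Raw coincidences rise with firing rate alone. The correction subtracts the
mean raw series of 200 surrogate data sets in which every dLGN spike is
displaced by an independent draw from ±{2.0, 2.5, …, 10.0} ms (uniform over
the two-sided set; offsets below 2 ms are excluded because they would not
reliably break a 4.5 ms coincidence). The jitter preserves each spike's
identity, the spike count, and the coarse rate profile (PSTH at 25 ms is
statistically unchanged), so the subtraction removes exactly the
rate-expected coincidence level. The corrected series is then smoothed
with a centred 4.5 ms boxcar (edges renormalised by kernel overlap). Only
dLGN spikes are jittered, for consistency with the statistical tests
below; a flag enables jittering both trains.

When a region contributes several units they are pooled into one spike
train per region before analysis (a per-pair mode is available through the
API by passing single-unit trains).

The event-triggered average of the corrected series (mean ± SE across
trials) exposes stimulus-locked rhythmicity; the synchrony spectrogram
treats the corrected series as a uniformly sampled signal (the 0.5 ms grid
is 2 kHz), runs it through the same filter bank, and event-averages
envelopes with a pre-stimulus percent-change baseline.

*Reading a peak frequency off the spectrogram.* The corrected series'
noise floor is shot noise shaped by the 4.5 ms counting window and the
4.5 ms smoothing (a sinc² envelope falling with frequency). Percent-change
normalisation divides the response by this falling floor, which tilts the
map upward in frequency: on sessions with a programmed narrowband rhythm,
the single-pixel 2-D argmax sits ~2–5 Hz above the true locking frequency
with ±2 Hz scatter between realisations. `TimeFrequencyMap.peak_frequency`
therefore averages the map over a latency range before taking the argmax
over frequency; over the 0–0.3 s response epoch this recovers a
programmed 68 Hz rhythm to within 0–3 Hz (still slightly high, for the
same floor-shape reason). The event-triggered waveform's spectrum does not
share the bias and recovers the programmed frequency within ~1 Hz.

## Synchrony–LFP correlation and the band test

Gray-screen and checkerboard epochs are analysed separately: checkerboard
segments are [onset, onset + 0.5 s), gray is the remaining time minus a
0.5 s guard after each response.

`xcorr_synchrony_lfp` computes, per frequency band and lag (±50 ms at
0.5 ms steps), the Pearson correlation between the corrected synchrony
series and the *signed* band-passed V1 voltage (amplitude × cos phase) at
the lagged time, restricted to sample pairs that both fall inside the
condition's segments. The signed voltage rather than the envelope is used
because an oscillatory, phase-resolved correlation (alternating peaks and
troughs at the gamma period) is the signature of interest. All lagged
sums are computed with FFTs over masked series, so segment handling is
exact rather than windowed.

`band_monte_carlo_test` tests the 50–90 Hz band: the observed lag curve is
compared with 1000 surrogate curves, each rebuilt from a dLGN-jittered
spike train (V1 spikes untouched, so phase locking of V1 spikes to its own
LFP cannot produce false positives). Pointwise 5th/95th surrogate
percentiles per lag form the thresholds; the observed curve is reported
with the per-lag surrogate median subtracted. Because the jitter preserves
the coarse rate, the rate-correction term of each surrogate series equals
that of the observed series, so the observed surrogate mean is reused
rather than re-estimated with nested surrogates — this keeps the test
O(n_surrogates) instead of O(n_surrogates²) with no change in the null.

## Synthetic sessions

No recordings ship with the package; `synthio` generates sessions with
known ground truth so every stage is testable. The generator emulates:

* per-region 1/f^α background noise (α = 1, unit SD — the amplitude
  reference for all other components);
* a shared narrowband gamma source (default 60 Hz, 3 Hz bandwidth, SD 0.5)
  during gray viewing, given to dLGN directly and to V1 delayed by the
  5 ms conduction delay, with a `coupling` fraction shared and the rest an
  independent same-band source. Sources are synthesised by spectral
  masking so their bandwidth is exactly as stated;
* checkerboard trials at 2.5–4 s intervals evoking a broadband 50–90 Hz
  source (SD 1.0) whose envelope is an alpha function peaking 112.5 ms
  after onset, while the narrowband source is suppressed by the same
  envelope; a 25–35 Hz low-gamma component (SD 0.7) is added to V1 only.
  The evoked source has a Gaussian spectral peak (default σ = 10 Hz)
  centred 8 Hz above the gray narrowband frequency — evoked high gamma
  sits higher in frequency than the narrowband oscillation — and half of
  it is a fixed per-session template replayed at each onset, emulating
  stimulus phase reset; without that locked fraction, trial averaging
  would cancel the evoked rhythm entirely and no stimulus-locked
  rhythmicity would exist to recover;
* dLGN spiking as an inhomogeneous Poisson process with von Mises phase
  locking to the dLGN gamma drive, `λ = r₀ · exp(κ cos φ) / I₀(κ)`
  (normalised so r₀ is the mean rate; defaults r₀ = 15 Hz, κ = 2.5),
  multiplied by a tonic contrast gain (1 + 2·envelope) and a burst gain
  (×4) in the 30–80 ms post-onset window with ~20 ms raised-cosine ramps —
  instantaneous rate steps would inject unphysical broadband splatter into
  the synchrony statistic;
* V1 spiking as probabilistic relay of dLGN spikes (p = 0.4, delay + 0.5 ms
  Gaussian timing jitter) plus an independent Poisson background at r₀.

`generate_null_session` keeps the LFP construction but draws both regions'
spikes as independent Poisson processes sharing a slow (≤ 5 Hz) log-normal
rate envelope: coincidence rates co-fluctuate, millisecond synchrony is
absent. It calibrates the rate correction and the band test. For
calibrating the PPC–amplitude test the right null is a coupled-LFP session
with `coupling = 0` and `evoked_lock = 0`: with stimulus phase reset
active in both regions, the phase *difference* is consistent across trials
even without any shared source, so PPC genuinely co-varies with amplitude
and the null hypothesis is false.

All stochastic draws flow from one seeded generator in a fixed order
(events; backgrounds; narrowband sources; evoked sources; low gamma; dLGN
units; V1 relay and background per unit), so a scenario and seed reproduce
a byte-identical session.

What the generator does **not** emulate: locomotion and movement
artifacts, electrode drift, spike-sorting errors, bursty (non-Poisson)
interspike statistics, laminar structure, eye movements, and any
mechanistic circuit dynamics — the construction is a phenomenological
fixture, not a model of how these oscillations arise. Passing tests
demonstrate that the analysis recovers programmed structure of this kind,
not that the biological claims hold in new data.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems: sessions of
30–220 s with 8–60 trials and 50–200 surrogates, versus 15-minute,
250-trial sessions and 1000–2000 surrogates for a full study-scale run.
Calibration statements (false-positive rates ≈ 5%) are means over 50 null
sessions with binomial confidence intervals at that replicate count.

Other numerical conventions: times are seconds in all files and APIs, with
millisecond parameters converted at operation boundaries; windows and
segments are half-open `[start, stop)`; spike times are strictly
ascending, unique at 0.05 ms; envelope/phase arrays are float32 (phase
precision ~1e-7 rad, far below any estimator noise); correlations are
clipped to [−1, 1] after floating-point rounding; constant series yield
NaN correlations and are excluded from significance calls; the pipeline
derives every stage's RNG from one master seed via `SeedSequence`, and
manifests carry config hashes and input checksums but no timestamps, so
identical runs produce identical bytes.

## Limitations

* The five-cycle filter rule limits spectral attribution at gamma to a few
  hertz; statements about narrow frequency differences are outside its
  resolution.
* The circular-shift PPC–amplitude test is anticonservative when the
  correlation window is short relative to the evoked response; the default
  window enforces the validated regime, but users supplying their own maps
  should keep the window ≳ 6× the response duration.
* The percent-change synchrony spectrogram carries the upward argmax bias
  described above; peak-frequency claims should rely on the
  event-triggered waveform spectrum or on maps of sufficient length.
* Pointwise significance (per frequency or per lag) is reported without
  multiplicity correction, matching the convention the analyses follow; a
  max-statistic correction would be stricter and can be layered on by
  thresholding at the surrogate distribution of the maximum instead.
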