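# gammasync

Analysis of thalamocortical gamma synchronization in paired dLGN–V1
recordings from awake mice. The package implements, as a tested and
reusable pipeline, four linked analyses:

1. **LFP time–frequency decomposition** — causal five-cycle FIR filter
   bank (0.5 Hz center steps, 0.5–5 Hz bandwidths) with Hilbert
   envelopes/phases, and event-locked maps of percent amplitude change
   from the pre-stimulus gray-screen baseline.
2. **Time-resolved pairwise phase consistency (PPC)** — for each frequency
   and 1 ms latency, the unbiased pairwise estimator
   `PPC = (|Σ e^{iθ}|² − N) / (N(N−1))` of the across-trial consistency of
   the dLGN→V1 phase offset, plus a circular-shift surrogate test of the
   per-frequency correlation between the PPC and amplitude time courses.
3. **Rate-corrected spike synchrony** — a continuous synchrony function:
   the product of V1 and conduction-delay-shifted dLGN spike counts in a
   sliding 4.5 ms window, minus the mean of 200 spike-jitter surrogates
   (±2–10 ms, 0.5 ms resolution), so rate increases alone cancel and only
   millisecond-precise coincidences remain; with event-triggered averaging
   and a rhythmicity spectrogram.
4. **Synchrony–LFP tests** — frequency × lag cross-correlation of the
   synchrony function with the signed band-passed V1 LFP, split by
   gray/checkerboard viewing, and a Monte Carlo test against dLGN-jittered
   surrogates for the 50–90 Hz high-gamma band.

Since no recordings are distributed, a synthetic-session generator
(`gammasync.synthio`) produces paired LFP + spike sessions with known
ground truth — shared narrowband/broadband gamma sources, conduction
delay, von Mises spike-phase locking, stimulus-evoked bursts — and matched
null sessions for calibrating every statistical test.

Intended users: systems neuroscientists analysing paired-region
extracellular recordings, and method developers who need a fully
synthetic, ground-truthed testbed for phase-synchrony and spike-synchrony
statistics.

## Worked example

```python
import numpy as np
from gammasync import (CouplingScenario, generate_session, pool_trains,
                       synchrony_series, event_triggered_synchrony,
                       synchrony_spectrogram)

session = generate_session(
    CouplingScenario(duration_s=80.0, n_trials=20, gamma_center=68.0,
                     evoked_peak_hz=68.0, seed=4))
v1 = pool_trains(session.spikes_v1, "V1")
lgn = pool_trains(session.spikes_lgn, "dLGN")

sync = synchrony_series(v1, lgn, rng=11)
print(f"{sync.raw.mean():.4f}", f"{sync.corrected.mean():+.4f}")

wave = event_triggered_synchrony(sync, session.events, window=(0.1, 0.4))
spec = synchrony_spectrogram(sync, session.events, window=(0.2, 0.4),
                             baseline_s=0.2)
i, j = np.unravel_index(np.argmax(spec.values), spec.values.shape)
print(spec.freqs[i], spec.times[j])
```

Running `python examples/04_spike_synchrony.py` (the same computation with
commentary) prints:

```
raw coincidence rate 0.0441 per window; corrected mean +0.0322 (excess over rate-expected coincidences)
event-triggered synchrony peaks at 50 ms post-stimulus (0.718 +- 0.274)
synchrony rhythmicity peaks near 67 Hz at 66 ms
```

Reading: of the ~0.044 coincidences per 4.5 ms window, ~0.032 exceed what
the firing rates alone predict — genuine millisecond synchrony from the
relayed spikes. It peaks just after the stimulus-evoked dLGN burst and
recurs rhythmically at the gamma frequency the spikes are locked to
(68 Hz programmed, 67 Hz recovered), the same band in which the V1 LFP
responds to contrast.

The other scripts in `examples/` walk through session simulation,
time–frequency maps, the PPC–amplitude test, the synchrony–LFP
correlation, and the full pipeline. A thin CLI mirrors them:

```bash
gammasync simulate --config scenario.yaml --out session/ --seed 1
gammasync run --session session/ --out results/ --seed 1
```

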