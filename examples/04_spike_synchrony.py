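"""Time-resolved, rate-corrected dLGN-V1 spike synchrony.

Raw coincidences (count product in a sliding 4.5 ms window, dLGN shifted
by the 5 ms conduction delay) confound precise timing with firing rate.
Subtracting the mean of 200 jitter surrogates (+-2-10 ms per-spike
displacement) leaves only millisecond-precise synchrony.
"""

import numpy as np
from scipy import signal as sps

from gammasync import (CouplingScenario, event_triggered_synchrony,
                       generate_session, pool_trains, synchrony_series,
                       synchrony_spectrogram)

session = generate_session(
    CouplingScenario(duration_s=80.0, n_trials=20, gamma_center=68.0,
                     evoked_peak_hz=68.0, seed=4))
v1 = pool_trains(session.spikes_v1, "V1")
lgn = pool_trains(session.spikes_lgn, "dLGN")

sync = synchrony_series(v1, lgn, rng=11)
print(f"raw coincidence rate {sync.raw.mean():.4f} per window; "
      f"corrected mean {sync.corrected.mean():+.4f} "
      f"(excess over rate-expected coincidences)")

wave = event_triggered_synchrony(sync, session.events, window=(0.1, 0.4))
peak = np.argmax(wave.mean)
print(f"event-triggered synchrony peaks at "
      f"{wave.latencies[peak] * 1e3:.0f} ms post-stimulus "
      f"({wave.mean[peak]:.3f} +- {wave.se[peak]:.3f})")

spec = synchrony_spectrogram(sync, session.events, window=(0.2, 0.4),
                             baseline_s=0.2)
i, j = np.unravel_index(np.argmax(spec.values), spec.values.shape)
print(f"synchrony rhythmicity peaks near {spec.freqs[i]:.0f} Hz "
      f"at {spec.times[j] * 1e3:.0f} ms")
# Synchronous spikes arrive rhythmically at the gamma frequency the dLGN
# spikes are locked to, echoing the evoked high-gamma LFP oscillation.
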