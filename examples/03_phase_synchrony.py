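"""Time-resolved dLGN-V1 phase synchronization and its link to amplitude.

Pairwise phase consistency (PPC) is the unbiased mean cosine of all
pairwise differences of the across-trial phase offsets theta_V1 -
theta_dLGN.  Correlating its time course with the V1 amplitude time course
per frequency, against circular-shift surrogates, asks which V1
oscillations grow specifically when V1 is phase-locked to the thalamus.
"""

import numpy as np

from gammasync import (CouplingScenario, analytic_decompose,
                       design_filter_bank, event_locked_amplitude_change,
                       fisher_average, generate_session,
                       ppc_amplitude_correlation, time_resolved_ppc)

session = generate_session(CouplingScenario(duration_s=60.0, n_trials=15,
                                            coupling=0.8, seed=2))
bank = design_filter_bank(session.lfp_v1.fs, 45.0, 95.0)
dec_v1 = analytic_decompose(session.lfp_v1, bank)
dec_lgn = analytic_decompose(session.lfp_lgn, bank)

window = (0.75, 1.25)  # wide window so the shift surrogates are valid
ppc_map = time_resolved_ppc(dec_v1, dec_lgn, session.events, window=window)
amp_map = event_locked_amplitude_change(dec_v1, session.events,
                                        window=window)
result = ppc_amplitude_correlation(ppc_map, amp_map, n_surrogates=2000,
                                   rng=0)

in_band = (result.freqs >= 50) & (result.freqs <= 90)
print(f"significant positive PPC-amplitude correlation at "
      f"{int(result.significant_pos[in_band].sum())} of {in_band.sum()} "
      f"frequencies inside 50-90 Hz")
print(f"peak evoked frequency {result.peak_freq:.1f} Hz; phase synchrony "
      f"explains R^2 = {result.r_squared_at_peak:.2f} of its amplitude "
      f"modulation there")
print(f"Fisher-averaged r inside the band: "
      f"{fisher_average(result.r[in_band]):.3f}")
# With coupling = 0.8 the driven high-gamma band shows strong positive
# correlations: V1 gamma grows exactly when it synchronizes with dLGN.
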