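"""Correlating spike synchrony with band-limited V1 LFP oscillations.

Splits the session into gray-screen and checkerboard epochs, cross-
correlates the corrected synchrony series with the signed band-passed V1
voltage per frequency and lag, and runs the dLGN-jitter Monte Carlo test
on the 50-90 Hz band.
"""

import numpy as np

from gammasync import (CouplingScenario, analytic_decompose,
                       band_monte_carlo_test, design_filter_bank,
                       generate_session, pool_trains, split_by_condition,
                       synchrony_series, xcorr_synchrony_lfp)

session = generate_session(
    CouplingScenario(duration_s=80.0, n_trials=20, seed=7))
span = (0.0, session.truth.duration_s)
gray, checker = split_by_condition(session.events, span)
print(f"gray time {gray.total_s():.0f} s, "
      f"checkerboard time {checker.total_s():.0f} s")

v1 = pool_trains(session.spikes_v1, "V1")
lgn = pool_trains(session.spikes_lgn, "dLGN")
sync = synchrony_series(v1, lgn, rng=3)

bank = design_filter_bank(session.lfp_v1.fs, 45.0, 95.0)
dec_v1 = analytic_decompose(session.lfp_v1, bank)
xc = xcorr_synchrony_lfp(sync, dec_v1, gray, max_lag_ms=50.0)
i, j = np.unravel_index(np.nanargmax(np.abs(xc.r)), xc.r.shape)
print(f"gray: peak |r| = {abs(xc.r[i, j]):.3f} at {xc.freqs[i]:.1f} Hz, "
      f"lag {xc.lags_ms[j]:+.1f} ms")
# During gray viewing the correlation concentrates at the narrowband gamma
# frequency; checkerboard epochs spread it across the broadband response.

for seg in (gray, checker):
    bt = band_monte_carlo_test(session.lfp_v1, v1, lgn, seg,
                               band=(50.0, 90.0), n_surrogates=1000, rng=5,
                               sync=sync)
    print(f"{seg.condition}: {int(bt.significant_pos.sum())} significant "
          f"peaks and {int(bt.significant_neg.sum())} troughs across lags "
          f"(1000 dLGN-jitter surrogates)")
# Alternating significant peaks and troughs at gamma-period spacing are the
# signature of spike synchrony riding a particular phase of the oscillation.
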