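import numpy as np
import pytest

from gammasync import (CouplingScenario, SpikeTrain, generate_session,
                       pool_trains, synchrony_series)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def poisson_train(rng, rate_hz, duration_s, region="V1", unit_id="u0"):
    """Homogeneous Poisson spike train on [0, duration_s)."""
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    t = t[np.concatenate([[True], np.diff(t) > 1e-4])] if t.size else t
    return SpikeTrain(t, region=region, unit_id=unit_id,
                      span=(0.0, duration_s))


@pytest.fixture(scope="session")
def locked68_session():
    """Coupled session with 68 Hz gamma and locked spiking, with its pooled
    trains and jitter-corrected synchrony series (shared: it is expensive)."""
    sc = CouplingScenario(duration_s=80.0, n_trials=20, gamma_center=68.0,
                          evoked_peak_hz=68.0, seed=4)
    ses = generate_session(sc)
    v1 = pool_trains(ses.spikes_v1, "V1")
    lgn = pool_trains(ses.spikes_lgn, "dLGN")
    sync = synchrony_series(v1, lgn, rng=11)
    return ses, v1, lgn, sync
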