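import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import hismatch as hm


@pytest.fixture(scope="session")
def space():
    return hm.make_default_space()


@pytest.fixture(scope="session")
def small_run(space):
    """A small but complete 3-wave synthetic calibration shared across tests."""
    cfg = hm.WaveConfig(
        n_initial_train=60, n_initial_val=12, n_initial_test=6,
        n_per_wave=25, n_candidates=600, n_reference=600,
        thresholds=(3.2, 3.2, 3.0), seed=5, restarts=2,
    )
    patient = hm.make_patient(space, seed=21, c=0.10)
    sim = hm.make_simulator(space)
    model = hm.HistoryMatching(space, sim, patient.targets, cfg, truth=patient.u_star)
    results = model.fit()
    return {"results": results, "patient": patient, "simulator": sim, "config": cfg}


@pytest.fixture(scope="session")
def trained_1d_bank():
    """A near-exact noise-free emulator bank for f(x) = x on [0, 1]."""
    X = np.linspace(0, 1, 15)[:, None]
    import pandas as pd

    Y = pd.DataFrame({"y": X.ravel()})
    return hm.fit_bank(X, Y, noise_free=True, restarts=3, seed=0)
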