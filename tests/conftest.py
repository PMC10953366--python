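import numpy as np
import pytest

import pygrics as pg


@pytest.fixture(scope="session")
def geometry32():
    return pg.Geometry(32, 32, (1.0, 1.0), 3.0)


@pytest.fixture(scope="session")
def phantom64():
    """Seeded 64x64 phantom + support mask, shared across tests."""
    return pg.make_phantom(64, seed=7)


@pytest.fixture(scope="session")
def moving_dataset(phantom64):
    """Seeded moving-phantom acquisition: 4 coils, 6-state binned drive,
    5 px peak vertical motion, 150 s shot-by-shot Cartesian readout."""
    phantom, support = phantom64
    alpha = pg.make_alpha(phantom.geometry, "vertical", 5.0, seed=7)
    resp = pg.make_resp(150.0, period_s=4.1, seed=7)
    coils = pg.make_coils(4, phantom.geometry, seed=7)
    proto = pg.Protocol(lines_per_shot=1, shot_interval_s=150.0 / 64)
    ks, truth = pg.simulate_acquisition(
        phantom, alpha, resp, coils, proto, seed=7, support=support, binned_states=6
    )
    return {
        "phantom": phantom,
        "support": support,
        "alpha": alpha,
        "resp": resp,
        "coils": coils,
        "protocol": proto,
        "ks": ks,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def grics_result(moving_dataset):
    """Full joint reconstruction of the shared moving dataset (Ns=6)."""
    cfg = pg.GricsConfig(n_states=6)
    return pg.run_grics(moving_dataset["ks"], moving_dataset["resp"], cfg)


def pixel_rmse(img, reference):
    a = np.abs(np.asarray(img))
    a = a / a.max() * reference.max()
    return float(np.sqrt(np.mean((a - reference) ** 2)))


@pytest.fixture(scope="session")
def rmse_fn():
    return pixel_rmse
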