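import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY_SIM = {
    "simulation": {
        "g": 6,
        "stages": ["jointing", "heading"],
        "stage_means": {"jointing": 0.55, "heading": 0.72},
        "density_scale": 1e-9,
        "density_floor": 400.0,
    }
}


@pytest.fixture(scope="session")
def tiny_config():
    from canoheight.config import config_from_dict

    return config_from_dict(TINY_SIM)


@pytest.fixture(scope="session")
def tiny_run(tiny_config, tmp_path_factory):
    """One small end-to-end pipeline run shared across tests."""
    from canoheight.pipeline import run

    out = tmp_path_factory.mktemp("tiny_run")
    run(tiny_config, out, seed=42)
    return out


@pytest.fixture(scope="session")
def tiny_height_table(tiny_run):
    return pd.read_csv(tiny_run / "heights" / "plot_heights.csv")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
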