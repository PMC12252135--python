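import numpy as np
import pytest

from orchardmot import NoiseModel, ScenarioConfig, generate


@pytest.fixture
def nm():
    """Default noise model (w_p=1/20, w_v=1/160, lambda in [0.6, 1], gamma=0.01)."""
    return NoiseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_scene():
    """One short noisy scene shared by the heavier integration tests."""
    cfg = ScenarioConfig(n_frames=80, seed=42)
    bundle, truth = generate(cfg)
    return cfg, bundle, truth


def res_rows_to_seq(rows):
    """Tracking-result rows -> the (id, box) per-frame mapping metrics expect."""
    return {f: [(i, b) for i, b, _ in r] for f, r in rows.items()}
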