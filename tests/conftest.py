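import numpy as np
import pytest

from astroloco import synthdata


@pytest.fixture(scope="session")
def astro_recording():
    """One small astrocyte recording with drift and noise, shared by tests."""
    cfg = synthdata.ScenarioConfig(
        duration_s=60.0,
        fov=(48, 48),
        n_astro=1,
        astro_domain_radius_px=18,
        astro_soma_radius_px=5,
        mean_quiet_s=20.0,
        paired_run_prob=0.0,
        max_shift_px=3,
        seed=42,
    )
    return synthdata.simulate_recording(cfg)


@pytest.fixture(scope="session")
def neuro_recording():
    """One small neuronal recording with four activity units."""
    cfg = synthdata.ScenarioConfig.neuro_default(
        duration_s=180.0,
        fov=(48, 48),
        n_neuro_units=4,
        neuro_len_px=10,
        mean_quiet_s=40.0,
        paired_run_prob=0.0,
        seed=7,
    )
    return synthdata.simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
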