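import numpy as np
import pytest

from optomask.config import SessionConfig
from optomask.synth import generate_session
from optomask.timeline import build_timeline


@pytest.fixture(scope="session")
def timeline():
    return build_timeline()


def make_config(**kw):
    gt = kw.pop("ground_truth", {})
    defaults = dict(trials_per_cell=25, contrasts=(0.05, 0.1, 0.2, 0.4),
                    opto_powers=(0.6,))
    defaults.update(kw)
    defaults["ground_truth"] = gt
    return SessionConfig(**defaults)


DEFAULT_NOISE = dict(noise_sd=1.0, heartbeat_amplitude=1.0, motion_sd_px=0.1,
                     drift_ms_sd=0.01, drift_mk_sd=0.02)


@pytest.fixture(scope="session")
def noisy_session():
    """One 200-trial session with every artifact enabled, shared read-only."""
    cfg = make_config(ground_truth=dict(rho_true=0.5, **DEFAULT_NOISE))
    return generate_session(cfg, seed=11)


@pytest.fixture(scope="session")
def clean_session():
    """Artifact-free session (no noise, no motion, no heartbeat, no drift)."""
    cfg = make_config(ground_truth=dict(rho_true=0.5))
    return generate_session(cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_pre(noisy_session):
    from optomask.pipeline import preprocess_session
    return preprocess_session(noisy_session)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
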