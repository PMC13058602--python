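"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest

from padbp import SimConfig, process_pair, simulate_subject


@pytest.fixture(scope="session")
def clean_run():
    """Noiseless, artifact-free 120 s run with fixed PTT law and no tone jitter."""
    cfg = SimConfig(
        seed=11, duration=120.0, maneuvers=(), noise_sd=0.0, ptt_tone_sd=0.0, artifact_rate=0.0
    )
    chest, leg, truth = simulate_subject(cfg)
    return cfg, chest, leg, truth


@pytest.fixture(scope="session")
def clean_processed(clean_run):
    cfg, chest, leg, truth = clean_run
    pc, pl = process_pair(chest, leg)
    return cfg, pc, pl, truth


@pytest.fixture(scope="session")
def noisy_run():
    """Default-noise (SNR ~ 12) 120 s run, no maneuvers."""
    cfg = SimConfig(seed=12, duration=120.0, maneuvers=(), ptt_tone_sd=0.0)
    chest, leg, truth = simulate_subject(cfg)
    return cfg, chest, leg, truth


@pytest.fixture(scope="session")
def maneuver_run():
    """Run with one Valsalva + rest so BP actually varies."""
    cfg = SimConfig(seed=13, duration=120.0, maneuvers=("valsalva", "rest"))
    chest, leg, truth = simulate_subject(cfg)
    return cfg, chest, leg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
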