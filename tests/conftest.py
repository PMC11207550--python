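import numpy as np
import pytest

import nirtherm as nt
from nirtherm.phantoms import PhantomSpec, study_phantoms


def uniform_phantoms() -> list[PhantomSpec]:
    """Seven phantoms with identical composition but the standard step profiles.

    With one shared composition the temperature response is identical across
    phantoms, so a single linear calibration can be exact at zero noise.
    """
    return [
        PhantomSpec(p.phantom_id, 22.2, 9.7, 68.1, p.step_profile_C)
        for p in study_phantoms()
    ]


@pytest.fixture(scope="session")
def default_cfg() -> nt.GeneratorConfig:
    """Full study conditions, master seed 42."""
    return nt.GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    """Processed interchange table + ground-truth ledger at full study size."""
    recs, traces, ledger = nt.simulate_dataset(cfg=default_cfg)
    df = nt.process_dataset(recs, traces, default_cfg)
    return df, ledger


@pytest.fixture(scope="session")
def small_cfg() -> nt.GeneratorConfig:
    """Reduced cadence (7 frames x 4 recordings/step) for fast unit tests."""
    return nt.GeneratorConfig(frames_per_recording=7, recordings_per_step=4, seed=5)


@pytest.fixture(scope="session")
def small_noiseless(small_cfg):
    """Reduced, fully deterministic dataset (all noise amplitudes zero)."""
    cfg = small_cfg.noiseless()
    recs, traces, ledger = nt.simulate_dataset(cfg=cfg)
    df = nt.process_dataset(recs, traces, cfg)
    return cfg, recs, traces, ledger, df


@pytest.fixture(scope="session")
def uniform_noiseless_df():
    """Zero-noise dataset over equal-composition phantoms: exactly linear."""
    cfg = nt.GeneratorConfig(frames_per_recording=7, recordings_per_step=4, seed=3).noiseless()
    recs, traces, _ = nt.simulate_dataset(uniform_phantoms(), cfg)
    return nt.process_dataset(recs, traces, cfg)


def true_spectra(ledger) -> np.ndarray:
    return ledger[[f"true_a{k:02d}" for k in range(1, 28)]].to_numpy()
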