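from __future__ import annotations

import numpy as np
import pytest

import micardia as mc

FS = 250.0


@pytest.fixture(scope="session")
def small_paradigm() -> mc.ParadigmSpec:
    """A short session (one run of 12 trials) for I/O and pipeline tests."""
    return mc.ParadigmSpec(n_runs=1, trials_per_run=12)


@pytest.fixture(scope="session")
def paper_session():
    """One full paradigm session with all modalities and planted artifacts."""
    return mc.generate_session(seed=42, artifact_fraction=0.15)


@pytest.fixture(scope="session")
def small_session(small_paradigm):
    return mc.generate_session(small_paradigm, seed=7, artifact_fraction=0.25)


def sine_epochs(
    n_trials: int,
    n_samples: int,
    freq: float,
    rng: np.random.Generator,
    amplitude=1.0,
    t0: float = -5.0,
) -> mc.EpochSet:
    """Random-phase sinusoid trials (non-phase-locked narrowband activity)."""
    t = t0 + np.arange(n_samples) / FS
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (n_samples,))
    data = amp[None, :] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return mc.EpochSet(data=data, times=t, sample_rate_hz=FS)
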