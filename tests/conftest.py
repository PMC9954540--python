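import numpy as np
import pytest

from p300lab.evaluate import DEFAULT_CONFIG, _session_epochs
from p300lab.synth import P300Params, SessionDesign, generate_session

#: compact oddball design used by the slower end-to-end tests
SMALL_DESIGN = dict(
    n_targets=4,
    n_repetitions_per_target=4,
    flashes_per_repetition=6,
    target_flashes_per_repetition=2,
)


@pytest.fixture(scope="session")
def small_design() -> SessionDesign:
    return SessionDesign(**SMALL_DESIGN)


def make_epochs(seed=0, amplitude=5.0, noise_scale=1.0, design=None):
    """Simulate + filter + epoch one compact session."""
    cfg = {
        **DEFAULT_CONFIG,
        "seed": seed,
        "amplitude": amplitude,
        "noise_scale": noise_scale,
        "design": design if design is not None else SMALL_DESIGN,
    }
    return _session_epochs(cfg)


@pytest.fixture(scope="session")
def small_epochs():
    """High-ish SNR filtered epochs from the compact design (96 trials)."""
    return make_epochs(seed=11, amplitude=5.0, noise_scale=1.0)


@pytest.fixture(scope="session")
def null_epochs():
    """Same design with zero evoked amplitude (pure noise)."""
    return make_epochs(seed=11, amplitude=0.0, noise_scale=1.0)


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    a = rng.standard_normal((n, n)) * scale
    return a @ a.T + n * np.eye(n)
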