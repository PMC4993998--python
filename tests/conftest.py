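import numpy as np
import pytest

from fcfmtex.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six 64-px videos, ~8 frames each; big texture effect for signal tests."""
    return generate_cohort(
        SyntheticConfig(
            n_patients=6, frame_size=64, frames_median=8, frames_sigma=0.2,
            texture_effect=2.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Thirty 64-px videos with both classes, for evaluation-level tests."""
    return generate_cohort(
        SyntheticConfig(
            n_patients=30, frame_size=64, frames_median=5, frames_sigma=0.0,
            texture_effect=2.0, seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
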