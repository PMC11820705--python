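import numpy as np
import pytest

from capsloc.simulate import SimulationConfig, generate_stream, uniform_confusion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_case():
    """One 20,000-frame stream at 5% uniform misclassification."""
    cfg = SimulationConfig(
        n_frames=20_000, confusion=uniform_confusion(0.05), seed=7
    )
    return generate_stream(cfg, video_id="noisy")


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free three-segment stream with sharp boundaries."""
    cfg = SimulationConfig(
        n_frames=12_000, boundary_blur=0, concentration=500.0, seed=3
    )
    return generate_stream(cfg, video_id="clean")


def random_probability_rows(rng, n):
    """Valid (n, 3) probability matrix via Dirichlet draws."""
    return rng.dirichlet([1.0, 1.0, 1.0], size=n)
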