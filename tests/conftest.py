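import numpy as np
import pytest

from ihcquant import SlideSpec, StainProfile, generate_slide
from ihcquant.synth import annotations_from_truth


@pytest.fixture(scope="session")
def profile():
    return StainProfile.default()


@pytest.fixture(scope="session")
def sparse_tile():
    """50 well-separated nuclei, low noise: the easy detection fixture."""
    spec = SlideSpec(
        n_cells=50, width=384, height=384, positive_fraction=0.4,
        touching_fraction=0.0, noise_sd=1.0, seed=42,
    )
    img, truth = generate_slide(spec)
    return img, truth, annotations_from_truth(truth)


@pytest.fixture(scope="session")
def blank_tile():
    img, _ = generate_slide(SlideSpec(n_cells=0, width=128, height=128, seed=0))
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
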