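import numpy as np
import pytest

from semsharp import SceneSpec, decompose, make_blur_series, score_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blur_series():
    """One graded-blur series at default conditions (shared, read-only)."""
    return make_blur_series(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def scored_series(blur_series):
    """QualityRecords (without Q) for the shared blur series."""
    return [score_micrograph(img) for img in blur_series.images]


@pytest.fixture(scope="session")
def sharp_and_blurred(blur_series):
    """Cartoon components of the sharp and sigma_b=2 images of one scene."""
    sharp = decompose(blur_series.images[0].to_canonical())
    blurred = decompose(blur_series.images[2].to_canonical())
    return sharp, blurred
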