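import numpy as np
import pytest

from pdl1tps import default_scheme
from pdl1tps.synthetic import SyntheticSlideSpec, generate_slide, slide_spec_for_tps


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_slide():
    """One 256x256 synthetic slide with ~25% true TPS, plus ground truth."""
    spec = slide_spec_for_tps(25.0, width=256, height=256, seed=3)
    image, truth = generate_slide(spec)
    return image, truth


@pytest.fixture(scope="session")
def tumor_only_slide():
    """Slide containing only positive tumor and background."""
    spec = SyntheticSlideSpec(
        width=128, height=128, class_fractions={"tc_pos": 0.5}, seed=7
    )
    image, truth = generate_slide(spec)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
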