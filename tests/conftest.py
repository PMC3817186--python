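import numpy as np
import pytest

from dermcadx.imaging import LesionMask, MacroImage, RegionPair, make_region_pair
from dermcadx.synthetic import (
    analytic_fixtures,
    benign_config,
    generate_lesion_image,
    malignant_config,
)


@pytest.fixture(scope="session")
def fixtures():
    return analytic_fixtures()


@pytest.fixture(scope="session")
def benign_pair():
    image, mask, _ = generate_lesion_image(benign_config(), seed=7)
    return make_region_pair(image, mask)


@pytest.fixture(scope="session")
def malignant_pair():
    image, mask, _ = generate_lesion_image(malignant_config(), seed=7)
    return make_region_pair(image, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
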