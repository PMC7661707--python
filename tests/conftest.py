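import numpy as np
import pytest

from glioresponse.datatypes import CONTROL, TREATED
from glioresponse.synthetic import CohortSpec, GroundTruthSources, make_cohort, make_sources


@pytest.fixture(scope="session")
def sources3() -> GroundTruthSources:
    return make_sources(3, 256, seed=7)


@pytest.fixture(scope="session")
def small_cohort(sources3):
    """8 subjects, 64px images, 10x10 grids — shared read-only cohort."""
    spec = CohortSpec(
        n_control=4, n_treated=4, image_size=64, spectrum_length=256,
        noise_sd=0.02, seed=11,
    )
    return make_cohort(spec, sources3)


@pytest.fixture(scope="session")
def disjoint_cohort(sources3):
    """Zero-noise cohort whose class mixing distributions have disjoint support."""
    spec = CohortSpec(
        n_control=4, n_treated=4, image_size=64, spectrum_length=256,
        noise_sd=0.0, seed=13,
        class_mixing={
            TREATED: np.array([1.0, 0.0, 1.0]),
            CONTROL: np.array([0.0, 1.0, 0.0]),
        },
    )
    return make_cohort(spec, sources3)
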