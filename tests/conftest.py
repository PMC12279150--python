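import warnings

import numpy as np
import pytest

from tavimorph.atlas import AtlasConfig, estimate_atlas
from tavimorph.synthetic import GeneratorConfig, make_template_mesh, \
    sample_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_template():
    """Coarse idealized aortic root (fast geometry fixture)."""
    mesh, frame = make_template_mesh(GeneratorConfig(n_rings=10,
                                                     n_azimuth=10))
    return mesh, frame


@pytest.fixture(scope="session")
def cohort10():
    """Ten-subject synthetic cohort at desk-scale mesh resolution."""
    cfg = GeneratorConfig(n=10, n_rings=14, n_azimuth=12)
    return sample_cohort(cfg, seed=3)


@pytest.fixture(scope="session")
def fitted_atlas(cohort10):
    """Atlas estimated on the ten-subject cohort (shared, expensive)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atlas, report = estimate_atlas(
            cohort10.meshes, AtlasConfig(max_rounds=2, max_iter=120),
            grid=cohort10.ground_truth.grid)
    return atlas, report
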