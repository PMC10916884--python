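import numpy as np
import pytest

from foveaspec import synthetic
from foveaspec.synthetic import FovealShapeParams


@pytest.fixture(scope="session")
def flat_shape():
    return FovealShapeParams(pit_depth_um=0.0, os_elongation_um=0.0,
                             onl_thickening_um=0.0)


@pytest.fixture(scope="session")
def flat_seg(flat_shape):
    return synthetic.generate_layer_profiles(flat_shape)


@pytest.fixture(scope="session")
def flat_img(flat_seg):
    return synthetic.render_bscan(flat_seg, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def specialized_shape():
    # deep pit, elongated OS, thick foveal ONL: a fully formed fovea
    return FovealShapeParams()


@pytest.fixture(scope="session")
def specialized_seg(specialized_shape):
    return synthetic.generate_layer_profiles(specialized_shape)


@pytest.fixture(scope="session")
def specialized_img(specialized_seg):
    return synthetic.render_bscan(specialized_seg, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_img(specialized_seg):
    # noise at 1% of the unit peak band intensity
    return synthetic.render_bscan(specialized_seg, noise_sd=0.01, seed=42)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return synthetic.generate_cohort(
        synthetic.CohortParams(n_participants=200, noise_sd_logmar=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    return synthetic.generate_cohort(
        synthetic.CohortParams(n_participants=74, seed=5)
    )
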