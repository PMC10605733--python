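import numpy as np
import pytest

import bpspect as b


@pytest.fixture(scope="session")
def default_study():
    """One default phantom with a +2-T2-voxel header offset."""
    spec = b.default_phantom_spec(seed=11, t2_offset_voxels=(2, 0))
    return b.generate_phantom(spec, patient_id="fixture")


@pytest.fixture(scope="session")
def registered(default_study):
    cube, masks = b.register_study(
        default_study.sequences,
        masks={
            "prostate": default_study.prostate_mask,
            "tumor": default_study.tumor_mask,
        },
    )
    return cube, masks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, dim=3, scale=1.0):
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T + dim * np.eye(dim))
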