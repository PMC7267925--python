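import numpy as np
import pytest

from restconn.synth import SynthConfig, generate_cohort
from restconn.volumes import BoldRun, MaskSet, MotionTrace


def small_synth_config(**overrides) -> SynthConfig:
    """Desk-scale synthetic config shared by the slower integration tests."""
    defaults = dict(
        grid_shape=(14, 14, 10),
        voxel_size_mm=3.0,
        n_timepoints=120,
        n_subjects=8,
        seed_center_mm=(0.0, 9.0, 0.0),
        target_centers_mm=((0.0, -9.0, 0.0), (9.0, 9.0, 0.0)),
        region_radius_mm=5.0,
        rng_seed=0,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_synth_config()
    return config, generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def identity_run(rng):
    """Tiny 4-D run on an identity-affine grid for unit tests."""
    data = rng.normal(100.0, 1.0, (6, 6, 4, 40))
    return BoldRun(data=data, tr_seconds=2.0, affine=np.eye(4), subject_id="sub-01")


@pytest.fixture()
def identity_masks(identity_run):
    shape = identity_run.shape
    brain = np.ones(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    wm[1:3, 1:3, 1:3] = True
    csf[4:6, 4:6, 1:3] = True
    gm = brain & ~wm & ~csf
    return MaskSet(brain=brain, gm=gm, wm=wm, csf=csf, affine=np.eye(4))


@pytest.fixture()
def random_motion(rng):
    steps = np.column_stack([rng.normal(0, 0.02, (40, 3)), rng.normal(0, 4e-4, (40, 3))])
    steps[0] = 0
    return MotionTrace(params=np.cumsum(steps, axis=0))
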