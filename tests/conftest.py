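import numpy as np
import pytest

from fcvessel import (
    PhantomSpec,
    Scene,
    TubeSegment,
    default_branching_spec,
    generate_phantom,
    mask_volume,
)

#: seed voxel on the trunk axis of the default branching phantom
TRUNK_SEED = (32, 32, 16)


@pytest.fixture(scope="session")
def branching_phantom():
    """Default branching-tree phantom (blurred, noisy), one fixed seed."""
    return generate_phantom(default_branching_spec(1))


@pytest.fixture(scope="session")
def branching_truth_volume_ml(branching_phantom):
    return mask_volume(branching_phantom.truth).volume_ml


def make_two_level_tube(
    shape=(40, 40, 40),
    vessel=180,
    background=80,
    radius=3.0,
    z0=4.0,
    z1=36.0,
):
    """Noiseless, unblurred two-level tube phantom along z through the center."""
    c = float(shape[0] // 2)
    spec = PhantomSpec(
        shape=shape,
        background_mean=background,
        background_sd=0.0,
        vessel_mean=vessel,
        vessel_sd=0.0,
        blur_sigma_mm=0.0,
        noise_sd=0.0,
        tree=[TubeSegment((c, c, z0), (c, c, z1), radius)],
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_level_tube():
    return make_two_level_tube()


def random_scene(rng, shape=(4, 4, 3)):
    return Scene(rng.integers(0, 256, size=shape).astype(np.uint8))
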