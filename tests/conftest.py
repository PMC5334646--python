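import numpy as np
import pytest

import spheroidkit as sk
from spheroidkit.phantoms import sample_ball_points


@pytest.fixture(scope="session")
def small_phantom():
    """A 60-nucleus phantom (stack + exact ground truth), isotropic."""
    spec = sk.PhantomSpec(n_nuclei=60, spheroid_radius=42.0, seed=1)
    stack, gt = sk.generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def small_phantom_image(small_phantom):
    _, stack, _ = small_phantom
    return sk.prepare_image(stack, z_scaling_factor=1.0, image_scaling_factor=1.0)


@pytest.fixture(scope="session")
def ball_points_2000():
    """2000 points uniform in a radius-63 ball (origin-centred)."""
    return sample_ball_points(2000, 63.0, seed=0)


@pytest.fixture(scope="session")
def ball_surface(ball_points_2000):
    return sk.build_alpha_shape(ball_points_2000, alpha=90.0)
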