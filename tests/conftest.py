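import numpy as np
import pytest

from palatesup.phantom import PhantomSpec, generate_phantom, rotation_about
from palatesup.transforms import RigidTransform


def known_pose(angle_deg: float = 8.0, translation=(2.0, -3.0, 1.5)) -> RigidTransform:
    """A repeatable global acquisition pose within the validated envelope
    (rotation <= 10 degrees, translation <= 5 mm)."""
    rot = rotation_about([0.3, 0.5, 0.8], angle_deg, center=[0.0, 0.0, 0.0])
    return RigidTransform(rot.rotation, rot.translation + np.asarray(translation))


@pytest.fixture(scope="session")
def null_bundle():
    """Noiseless phantom with identity pose and identity treatment."""
    return generate_phantom(PhantomSpec(surface_noise_sd=0.0))


@pytest.fixture(scope="session")
def posed_bundle():
    """Noiseless phantom whose T2 acquisition carries a known rigid pose."""
    return generate_phantom(
        PhantomSpec(surface_noise_sd=0.0, global_pose=known_pose())
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
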