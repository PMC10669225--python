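import numpy as np
import pytest

from artikin.articulator import AnatomicalLandmarks
from artikin.synthetic import generate_patient


@pytest.fixture(scope="session")
def patient():
    """One representative virtual patient shared by read-only tests."""
    return generate_patient(42)


@pytest.fixture(scope="session")
def landmarks():
    """Hand-written canonical landmarks: condyles on the hinge axis,
    incisal point anterior-inferior."""
    return AnatomicalLandmarks(
        condyle_right=[55.0, 0.0, 0.0],
        condyle_left=[-55.0, 0.0, 0.0],
        anterior_point=[0.0, 80.0, 0.0],
        incisal_point=[0.0, 95.0, -40.0],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rigid_transform(rng, max_angle=np.pi, max_shift=50.0):
    """Uniformly random proper rigid transform (helper, not a fixture)."""
    from artikin.transforms import FramedTransform

    a = rng.normal(size=3)
    a /= np.linalg.norm(a)
    angle = rng.uniform(-max_angle, max_angle)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    r = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = rng.uniform(-max_shift, max_shift, size=3)
    return FramedTransform(m)
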