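import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrseg.phantom import (
    DME,
    DW,
    T2SW,
    T2W,
    GridSpec,
    PhantomSpec,
    RigidParams,
    generate_study,
)
from mrseg.preprocess import preprocess_study
from mrseg.volume import ImageVolume

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_sphere_mask(radius_mm=15.0, n=40, spacing=(1.0, 1.0, 1.0)):
    """Sphere mask of the given radius centered on an n^3 grid."""
    zi, yi, xi = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    c = (n - 1) / 2
    sx, sy, sz = spacing
    r2 = ((xi - c) * sx) ** 2 + ((yi - c) * sy) ** 2 + ((zi - c) * sz) ** 2
    return ImageVolume(r2 <= radius_mm**2, spacing)


@pytest.fixture(scope="session")
def sphere30():
    """A 30 mm sphere (radius 15 mm) on a 1 mm grid."""
    return make_sphere_mask(15.0, 40)


def tiny_spec(**overrides) -> PhantomSpec:
    """A very coarse phantom for fast unit tests."""
    g = GridSpec((16, 16, 12), (2.5, 2.5, 2.5))
    base = dict(
        grids={T2W: g, T2SW: g, DW: g, DME: g},
        tumor_semiaxes_mm=(6.0, 5.5, 5.0),
        misalignment={k: RigidParams() for k in (T2W, T2SW, DW, DME)},
        observer_amplitude_mm=2.0,
    )
    base.update(overrides)
    return PhantomSpec.small(**base)


@pytest.fixture(scope="session")
def small_study():
    """One coarse study with the default split dynamic acquisition."""
    return generate_study(tiny_spec(), seed=11)


@pytest.fixture(scope="session")
def prep_study(small_study):
    """The same study preprocessed (no transform estimation: aligned)."""
    return preprocess_study(small_study, margin_mm=8.0, estimate_transforms=False)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three preprocessed coarse studies for cross-validation tests."""
    cohort = []
    for i in range(3):
        s = generate_study(tiny_spec(), seed=30 + i)
        cohort.append(preprocess_study(s, margin_mm=8.0, estimate_transforms=False))
    return cohort
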