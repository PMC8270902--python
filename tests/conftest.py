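import pytest

from idrark import (
    AnalysisConfig,
    LesionSpec,
    make_phantom_anatomy,
    simulate_cohort,
)

SMALL_SHAPE = (20, 24, 20)


@pytest.fixture(scope="session")
def small_anatomy():
    """Compact phantom used by most unit tests (2 lobes/hemisphere)."""
    return make_phantom_anatomy(SMALL_SHAPE, voxel_mm=2.0,
                                n_lobes_per_hemisphere=2, rng_seed=0)


@pytest.fixture(scope="session")
def anatomy():
    """Full-size phantom (the grid the protocol assumes, 2 mm iso)."""
    return make_phantom_anatomy((40, 48, 40), voxel_mm=2.0,
                                n_lobes_per_hemisphere=4, rng_seed=0)


@pytest.fixture()
def cfg():
    return AnalysisConfig(rng_seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_anatomy):
    """12 controls + 1 lesioned patient on the compact phantom."""
    lesion = LesionSpec(center=(14, 16, 10), radius_mm=6.0,
                        delta_md=0.3, delta_fa=0.3, delta_mk=0.3)
    return simulate_cohort(small_anatomy, 12, {"pat000": lesion}, rng_seed=77)
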