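import numpy as np
import pytest

from planrbe import (
    DoseGrid,
    Geometry,
    MotionKernel,
    PhantomSpec,
    Role,
    StructureMask,
    evaluate_cohort,
    make_cohort,
    make_phantom,
    paint_dose,
)


@pytest.fixture
def small_geo():
    return Geometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (10, 10, 10))


@pytest.fixture
def full_mask(small_geo):
    return StructureMask("all", Role.OTHER, small_geo, np.ones(small_geo.dims, bool))


def uniform_dose(geo, value, n_fractions=20):
    return DoseGrid(geo, np.full(geo.dims, float(value)), n_fractions)


@pytest.fixture
def default_phantom():
    spec = PhantomSpec()
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def phantom_case_plans():
    """One default phantom with all three painted plans."""
    spec = PhantomSpec(seed=1)
    structures = make_phantom(spec)
    doses = {plan: paint_dose(structures, plan, spec) for plan in
             ("plan1", "plan2", "plan3")}
    return spec, structures, doses


@pytest.fixture(scope="session")
def cohort_records():
    """The canonical seeded 10-case cohort, evaluated with and without
    motion.  Session-scoped: this is the expensive end-to-end fixture."""
    cohort = make_cohort(10, seed=1)
    records = evaluate_cohort(cohort, kernel=MotionKernel())
    return cohort, records
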