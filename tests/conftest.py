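import numpy as np
import pytest
from hypothesis import settings

from srsmetrics.grid import Lattice, ball_mask
from srsmetrics.phantom import PhantomSpec, make_radial_plan

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_lattice(n=25, h=1.0):
    o = -(n - 1) / 2.0 * h
    return Lattice((n, n, n), (h, h, h), (o, o, o))


@pytest.fixture(scope="session")
def lat25():
    return make_lattice(25)


@pytest.fixture(scope="session")
def sphere5(lat25):
    """Fractional mask of a 5 mm radius sphere on a 1 mm lattice."""
    return ball_mask(lat25, radius_mm=5.0, label="sphere5")


@pytest.fixture(scope="session")
def powerlaw_spec():
    """Concentric pure power-law phantom (k = 3) with an explicit prescription.

    The prescription isodose sits at 85% of the boundary dose, safely inside
    the falloff region, so every isodose any metric probes has a clean closed
    form.
    """
    return PhantomSpec(
        gtv_volume_cc=7.0,
        center_dose_ratio=1.8,
        interior_exponent=1.0,
        falloff_exponent=3.0,
        prescription_isodose_fraction=0.85,
    )


@pytest.fixture(scope="session")
def powerlaw_plan(powerlaw_spec):
    return make_radial_plan(powerlaw_spec)


@pytest.fixture(scope="session")
def offset_spec():
    """Radial phantom with internal heterogeneity, dose-focus offset and the
    clinical (near-minimum) prescription rule — the general-case fixture."""
    return PhantomSpec(
        gtv_volume_cc=7.0,
        center_dose_ratio=1.8,
        interior_exponent=1.0,
        falloff_exponent=3.0,
        dose_center_offset_mm=0.3,
    )


@pytest.fixture(scope="session")
def offset_plan(offset_spec):
    return make_radial_plan(offset_spec)
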