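import numpy as np
import pytest

from tumorclass.control import fit_control_band
from tumorclass.growth import GrowthCurve
from tumorclass.simulate import CONTROL_ARCHETYPE, simulate_cohort


def make_curve(animal_id, days, areas_mm2, **kw):
    return GrowthCurve(animal_id=animal_id, days=tuple(days),
                       areas_mm2=tuple(areas_mm2), **kw)


@pytest.fixture(scope="session")
def control_cohort():
    """Control-only synthetic cohort: single growth archetype, σ=0.1."""
    return simulate_cohort(n=50, specs=(CONTROL_ARCHETYPE,), seed=11)


@pytest.fixture(scope="session")
def control_band(control_cohort):
    return fit_control_band(list(control_cohort.curves))


@pytest.fixture(scope="session")
def mixed_cohort():
    """Default three-archetype cohort used by classifier tests."""
    return simulate_cohort(n=120, seed=5)
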