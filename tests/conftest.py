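import numpy as np
import pytest
from hypothesis import settings

import ppqtwin as pt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def compound():
    return pt.load_compound()


@pytest.fixture(scope="session")
def mean_phys():
    return pt.mean_physiology(26.0, 25.0)


@pytest.fixture(scope="session")
def sudan_schedule():
    return pt.schedule_hours("sudan")


@pytest.fixture(scope="session")
def default_profile(mean_phys, compound, sudan_schedule):
    """Three once-daily doses of the default piperaquine configuration for
    the mean 26-week physiology, sampled on the Sudan schedule."""
    dose = compound.salt_to_base(17.57 * mean_phys.body_weight)
    regimen = pt.DoseRegimen.once_daily(dose, 3, sudan_schedule)
    return pt.simulate(mean_phys, compound, regimen)
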