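import numpy as np
import pytest

from matrikin import synthetic_data as synth
from matrikin.config import RunConfig


@pytest.fixture(scope="session")
def trio():
    """Mother, father, child."""
    return synth.PedigreeSpec(("MO", "FA", "CH"), {"CH": ("MO", "FA")})


@pytest.fixture(scope="session")
def three_generations():
    """Grandmother GM -> mother MO -> son SON / daughter DAU, plus two
    unrelated founders."""
    return synth.PedigreeSpec(
        ("GM", "F0", "MO", "F1", "SON", "DAU", "U1", "U2"),
        {"MO": ("GM", "F0"), "SON": ("MO", "F1"), "DAU": ("MO", "F1")},
    )


@pytest.fixture(scope="session")
def mt_founder():
    return synth.make_mt_founder(seed=0)


@pytest.fixture(scope="session")
def damaged_stack(mt_founder):
    """A moderately deep damaged mt read stack with its truth sequence."""
    p = synth.SimReadParams(coverage=20.0, error=0.001, d0=0.4, lam=0.3, seed=11)
    return synth.simulate_mt_reads(mt_founder, p), mt_founder


@pytest.fixture(scope="session")
def linear_curve():
    return synth.make_cal_curve("linear", sigma=5.0)


@pytest.fixture(scope="session")
def plateau_curve():
    return synth.make_cal_curve("plateau", plateau_center_ce=1000.0,
                                plateau_width=150.0)


@pytest.fixture()
def config():
    return RunConfig(seed=0)
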