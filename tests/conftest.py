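import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from repressilator import model

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_n6():
    """Table-1 sweep family, 6-gene ring, at c = 5 (above the first Hopf)."""
    return model.preset("table1", n=6)


@pytest.fixture(scope="session")
def fig3_params():
    """The 18-gene reference ring (c1=2.6, c2=0.12, c3=0.2, c4=0.06)."""
    return model.preset("fig3")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100122)


@pytest.fixture(scope="session")
def n6_first_orbit(table1_n6):
    """Converged first-branch orbit of the 6-gene ring at c = 4.9."""
    from repressilator import orbits
    from repressilator.equilibria import find_hopf_points

    hb = find_hopf_points(table1_n6)[0]
    pc = table1_n6.with_c(hb.c_star * 1.05)
    y0, T0 = orbits.initial_guess_from_hopf(hb, pc)
    orb = orbits.shoot(y0, T0, pc, branch_id=1)
    return orbits.continue_branch(orb, 4.9, step=0.25)[-1]
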