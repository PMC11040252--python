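import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import morphglide as mg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model():
    """The default calibrated synthetic glider (seed 0)."""
    return mg.make_synthetic_model(seed=0)


@pytest.fixture(scope="session")
def trajectories():
    return mg.default_trajectories()


@pytest.fixture(scope="session")
def start_config():
    return mg.JointConfig(120.7, 105.3)


@pytest.fixture(scope="session")
def end_config():
    return mg.JointConfig(155.8, 167.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_constant_model(
    CL0=0.2,
    CLa=5.0,
    Cm0=0.05,
    Cma=-0.5,
    CD0=0.02,
    k_ind=0.05,
    CLq=3.0,
    Cmq=-12.0,
    Iyy=0.006,
):
    """A glider whose coefficient surfaces are constants: closed-form
    behaviour is easy to derive by hand, which makes it the workhorse for
    oracle tests."""
    c = mg.Poly2D.constant
    return mg.AeroModel(
        parameters=mg.BirdParameters(),
        surfaces=mg.CoefficientSurfaces(
            CL0=c(CL0), CLa=c(CLa), Cm0=c(Cm0), Cma=c(Cma),
            CD0=c(CD0), k_ind=c(k_ind), CLq=c(CLq), Cmq=c(Cmq),
        ),
        inertia=mg.InertiaSurfaces(Iyy=c(Iyy)),
    )


@pytest.fixture()
def constant_model():
    return make_constant_model()
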