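import numpy as np
import pytest
from hypothesis import settings

import broilervent as bv

settings.register_profile("default", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("default")


@pytest.fixture
def bird():
    return bv.BirdThermalParams()


@pytest.fixture
def registry():
    return bv.InletRegistry.default()


@pytest.fixture
def layout():
    return bv.ZoneLayout.default()


@pytest.fixture
def quiet_components():
    """House hardware with circulation fans removed (pure-advection tests)."""
    return bv.HouseComponents(
        circulation=bv.CirculationFan(intake_speed=0.0, count=0)
    )


def random_bird_draw(rng, ec_zero=False):
    """One random valid (params, env) pair for solver stress tests."""
    params = bv.BirdThermalParams(
        rt=rng.uniform(0.05, 0.4),
        rc=rng.uniform(0.05, 0.4),
        ra=rng.uniform(0.05, 0.4),
        rflr=rng.uniform(0.05, 0.5),
        rr=rng.uniform(0.08, 0.5),
        ec=0.0 if ec_zero else rng.uniform(0.0, 25.0),
        er=rng.uniform(0.0, 10.0),
        exposed=rng.uniform(0.2, 1.0),
    )
    env = bv.EnvironmentState(ta=rng.uniform(5.0, 38.0), v=rng.uniform(0.0, 3.0))
    return params, env


def constant_outdoor_schedule(end, fans_on, baffles, t_out, t_wb=None):
    ev = {"t": 0, "fans_on": fans_on, "baffles": baffles, "t_out": t_out}
    if t_wb is not None:
        ev["t_wb"] = t_wb
    return bv.parse_operational_log({"end": end, "events": [ev]})
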