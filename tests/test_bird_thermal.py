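"""Bird resistance-network model: solvers, sources, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import broilervent as bv
from conftest import random_bird_draw


def isothermal_setup():
    params = bv.BirdThermalParams(ec=0.0, er=0.0, ra=0.1)
    env = bv.EnvironmentState(ta=41.0, tflr=41.0, tr=41.0, v=0.0)
    return params, env


def test_isothermal_equilibrium_is_exact():
    """At core temperature with no latent losses, everything is at rest."""
    params, env = isothermal_setup()
    for sol in (
        bv.solve_bird_temperatures(params, env),
        bv.solve_bird_temperatures_direct(params, env),
    ):
        assert sol.converged
        assert sol.ts == pytest.approx(41.0, abs=1e-9)
        assert sol.tc == pytest.approx(41.0, abs=1e-9)
        for q in (sol.qt, sol.qc, sol.qa, sol.qflr, sol.qr):
            assert q == pytest.approx(0.0, abs=1e-9)


def test_initial_temperatures_split_core_air_gap_in_thirds():
    ts0, tc0 = bv.initial_temperatures(41.0, 26.0)
    assert ts0 == pytest.approx(36.0)
    assert tc0 == pytest.approx(31.0)


def test_direct_solution_closes_both_balances():
    """Back-substituted residuals of the closed-form solve are ~machine zero."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        params, env = random_bird_draw(rng)
        sol = bv.solve_bird_temperatures_direct(params, env)
        r1, r2 = sol.balance_residuals(params, env)
        assert abs(r1) < 1e-9
        assert abs(r2) < 1e-9


def test_iterative_solver_matches_direct_oracle():
    rng = np.random.default_rng(42)
    for _ in range(300):
        params, env = random_bird_draw(rng)
        direct = bv.solve_bird_temperatures_direct(params, env)
        iterative = bv.solve_bird_temperatures(params, env, tol=1e-9, max_iter=2000)
        assert iterative.converged
        assert iterative.ts == pytest.approx(direct.ts, abs=1e-6)
        assert iterative.tc == pytest.approx(direct.tc, abs=1e-6)


def test_respiration_grouping_flag_consistent_across_solvers():
    params = bv.BirdThermalParams(ra=0.12)
    env = bv.EnvironmentState(ta=24.0, v=0.8)
    d = bv.solve_bird_temperatures_direct(params, env, respiration_exposed=True)
    it = bv.solve_bird_temperatures(
        params, env, tol=1e-9, max_iter=2000, respiration_exposed=True
    )
    assert it.ts == pytest.approx(d.ts, abs=1e-6)
    # scaling respiration by the exposed fraction reduces the core load,
    # leaving the skin warmer than under the default grouping
    default = bv.solve_bird_temperatures_direct(params, env)
    assert d.ts > default.ts


@given(
    ta=st.floats(5.0, 38.0),
    rt=st.floats(0.05, 0.4),
    rc=st.floats(0.05, 0.4),
    ra=st.floats(0.05, 0.4),
    er=st.floats(0.0, 10.0),
    exposed=st.floats(0.2, 1.0),
)
def test_temperature_ordering_without_skin_evaporation(ta, rt, rc, ra, er, exposed):
    """With Ec=0 and air below core temperature, Ta <= Tc <= Ts <= Tb."""
    params = bv.BirdThermalParams(rt=rt, rc=rc, ra=ra, ec=0.0, er=er, exposed=exposed)
    env = bv.EnvironmentState(ta=ta)
    sol = bv.solve_bird_temperatures_direct(params, env)
    assert ta - 1e-9 <= sol.tc <= sol.ts + 1e-12 <= params.tb + 1e-9


def test_skin_evaporation_cools_the_skin():
    env = bv.EnvironmentState(ta=25.0, v=0.5)
    lo = bv.solve_bird_temperatures_direct(bv.BirdThermalParams(ec=5.0), env)
    hi = bv.solve_bird_temperatures_direct(bv.BirdThermalParams(ec=20.0), env)
    assert hi.ts < lo.ts


def test_sensible_flux_decreases_with_air_temperature():
    params = bv.BirdThermalParams()
    qa = [
        bv.solve_bird_temperatures_direct(params, bv.EnvironmentState(ta=ta, v=0.5)).qa
        for ta in np.linspace(10.0, 40.0, 13)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(qa, qa[1:]))


def test_nonconvergence_is_flagged_not_raised():
    params = bv.BirdThermalParams()
    sol = bv.solve_bird_temperatures(params, bv.EnvironmentState(ta=20.0), max_iter=2)
    assert not sol.converged
    assert sol.iterations == 2
    assert sol.residual > 0


@pytest.mark.parametrize(
    "kwargs",
    [
        {"rt": -0.1},
        {"rc": 0.0},
        {"exposed": 1.2},
        {"ac": 0.0},
        {"vz": -5.0},
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        bv.BirdThermalParams(**kwargs)


def test_invalid_solver_settings_rejected():
    params, env = bv.BirdThermalParams(), bv.EnvironmentState(ta=20.0)
    with pytest.raises(ValueError):
        bv.solve_bird_temperatures(params, env, tol=0.0)
    with pytest.raises(ValueError):
        bv.EnvironmentState(ta=20.0, v=-1.0)


def test_sensible_heat_source_reference_flock():
    """30,000 birds of 0.1 m2 at 10 W/m2 over the 587.25 m3 bird zone."""
    params = bv.BirdThermalParams(ac=0.1, nb=30_000, vz=587.25)
    assert bv.sensible_heat_source(params, 10.0) == pytest.approx(51.085, abs=1e-3)
    assert bv.sensible_heat_source(params, 0.0) == 0.0
    doubled = bv.BirdThermalParams(ac=0.1, nb=60_000, vz=587.25)
    assert bv.sensible_heat_source(doubled, 10.0) == pytest.approx(
        2 * bv.sensible_heat_source(params, 10.0)
    )


def test_drag_momentum_sink_reference_flock():
    params = bv.BirdThermalParams(nb=30_000, ap=0.05, cd=1.0, vz=587.25)
    env = bv.EnvironmentState(ta=20.0, v=1.0, rho=1.225)
    assert bv.drag_momentum_sink(params, env) == pytest.approx(-1.5645, abs=5e-4)
    assert bv.drag_momentum_sink(params, bv.EnvironmentState(ta=20.0, v=0.0)) == 0.0


@given(v=st.floats(0.01, 5.0))
def test_drag_is_quadratic_in_air_speed(v):
    params = bv.BirdThermalParams()
    one = bv.drag_momentum_sink(params, bv.EnvironmentState(ta=20.0, v=v))
    two = bv.drag_momentum_sink(params, bv.EnvironmentState(ta=20.0, v=2 * v))
    assert one <= 0.0
    assert two == pytest.approx(4.0 * one, rel=1e-12)


def test_velocity_dependent_boundary_layer_increases_heat_loss():
    """Faster air thins the boundary layer: more sensible flux (wind chill)."""
    params = bv.BirdThermalParams()  # default ra is velocity-dependent
    still = bv.solve_bird_temperatures_direct(params, bv.EnvironmentState(ta=22.0, v=0.0))
    windy = bv.solve_bird_temperatures_direct(params, bv.EnvironmentState(ta=22.0, v=2.0))
    assert windy.qa > still.qa
    ra = bv.mixed_convection_resistance()
    assert ra(2.0) < ra(0.0)
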