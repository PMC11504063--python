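"""Six-zone transient energy balance of a tunnel-ventilated house.

The house interior (2 lateral x 3 longitudinal zones, numbered 1-3
along one side from the end wall opposite the fans and 4-6 along the
other) is modelled as two chains of stirred tanks: fresh air enters
each zone through its own side-wall inlets (and through the cooling
pads at the far end when active), flows longitudinally far -> mid ->
near, and leaves through the tunnel fans at the near-zone temperature.
Each zone carries the flock's sensible-heat source, conduction through
its share of the envelope, and — while the tunnel fans are off — a
lateral mixing exchange driven by the ceiling circulation fans.

This is a deliberate reduced-order surrogate of the full 3-D flow
problem: it resolves the longitudinal thermal gradient and the
transient response to fan/baffle operation, not velocity or pressure
fields inside the zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .bird_thermal import (
    BirdThermalParams,
    EnvironmentState,
    sensible_heat_source,
    solve_bird_temperatures,
    solve_bird_temperatures_direct,
)
from .schedules_io import Schedule
from .ventilation_components import (
    CirculationFan,
    CoolingPad,
    FanCurve,
    InletRegistry,
    OperatingPoint,
    cooling_pad_outlet,
    solve_operating_point,
)

__all__ = [
    "ZoneLayout",
    "SimulationConfig",
    "HouseComponents",
    "HouseState",
    "SimulationResult",
    "step",
    "simulate",
]

N_ZONES = 6
ZONE_LABELS = (1, 2, 3, 4, 5, 6)
#: zone index by (side, section); sections ordered from the end wall
#: opposite the fans ("far") toward the fan wall ("near").
_ZONE_OF = {
    ("L", "far"): 0, ("L", "mid"): 1, ("L", "near"): 2,
    ("R", "far"): 3, ("R", "mid"): 4, ("R", "near"): 5,
}
#: upstream neighbour in the longitudinal chain (-1 = none, fed by
#: fresh air only).
_UPSTREAM = (-1, 0, 1, -1, 3, 4)
#: lateral zone pairs exchanged by the circulation fans.
_PAIRS = ((0, 3), (1, 4), (2, 5))
#: zones receiving the cooling-pad inflow (far end of both sides).
_PAD_ZONES = (0, 3)


@dataclass(frozen=True)
class ZoneLayout:
    """Per-zone geometry of the 2 x 3 zonal grid.

    Arrays are ordered by zone index 0-5 (labels 1-6).  ``air_volume``
    and ``bird_volume`` in m3, ``wall_area`` (exterior wall + roof
    share) in m2, ``cross_section`` (area for longitudinal through-flow
    of one lateral half) in m2.
    """

    air_volume: np.ndarray
    bird_volume: np.ndarray
    wall_area: np.ndarray
    cross_section: np.ndarray

    def __post_init__(self) -> None:
        for name in ("air_volume", "bird_volume", "wall_area", "cross_section"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_ZONES,):
                raise ValueError(f"{name} must have {N_ZONES} entries")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be > 0")
            object.__setattr__(self, name, arr)

    @classmethod
    def default(
        cls,
        length: float = 87.0,
        width: float = 15.0,
        eave: float = 3.5,
        ridge: float = 5.0,
        bird_height: float = 0.45,
    ) -> "ZoneLayout":
        """Layout from the envelope dimensions of the reference house.

        Gable cross-section = width*eave + width*(ridge-eave)/2, split
        into two lateral halves; the length is split into three equal
        sections.  Each zone's envelope share is its outer side wall
        plus half-roof slope, plus half an end wall for the far and
        near zones.
        """
        cross_house = width * eave + 0.5 * width * (ridge - eave)
        seg = length / 3.0
        half_width = width / 2.0
        slope = math.hypot(half_width, ridge - eave)
        vol = cross_house * seg / 2.0
        bird_vol = half_width * seg * bird_height
        side_wall = seg * eave
        roof = seg * slope
        end_wall = cross_house / 2.0
        wall = np.array([side_wall + roof] * N_ZONES)
        for z in (0, 3):  # far-end wall
            wall[z] += end_wall
        for z in (2, 5):  # fan-end wall
            wall[z] += end_wall
        return cls(
            air_volume=np.full(N_ZONES, vol),
            bird_volume=np.full(N_ZONES, bird_vol),
            wall_area=wall,
            cross_section=np.full(N_ZONES, cross_house / 2.0),
        )

    def inlet_matrix(self, registry: InletRegistry) -> np.ndarray:
        """(6, n_inlets) 0/1 matrix assigning each baffle to its zone."""
        m = np.zeros((N_ZONES, len(registry)))
        for j, (side, sec) in enumerate(zip(registry.sides, registry.sections)):
            key = (side, sec)
            if key not in _ZONE_OF:
                raise ValueError(f"cannot place inlet {registry.ids[j]}: {key}")
            m[_ZONE_OF[key], j] = 1.0
        return m


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical and physical settings of the zonal simulation.

    dt : schedule time step [s].  u_wall : envelope heat transmission
    coefficient [W m-2 K-1].  rho / cp : air density [kg m-3] and heat
    capacity [J kg-1 K-1].  t_init : uniform initial indoor temperature
    [degC] or a 6-vector.  substep_safety : fraction of the advective
    stability limit targeted by automatic sub-stepping; min_substeps
    forces a finer integration step (2 halves the effective dt) for
    refinement studies.
    fixed_sensible_source : when set, a constant volumetric bird-zone
    source [W m-3] replaces the bird model (0 disables bird heat).
    use_iterative_bird : evaluate the flock balance with the fixed-point
    scheme instead of the closed-form solve (slower, same answer).
    """

    dt: float = 1.0
    u_wall: float = 0.247
    rho: float = 1.2
    cp: float = 1006.0
    t_init: float | np.ndarray = 26.5
    substep_safety: float = 0.5
    min_substeps: int = 1
    max_substeps: int = 1000
    fixed_sensible_source: float | None = None
    use_iterative_bird: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.u_wall < 0:
            raise ValueError("u_wall must be >= 0")
        if self.rho <= 0 or self.cp <= 0:
            raise ValueError("rho and cp must be > 0")
        if not 0 < self.substep_safety <= 1:
            raise ValueError("substep_safety must be in (0, 1]")
        if self.min_substeps < 1:
            raise ValueError("min_substeps must be >= 1")

    def initial_temps(self) -> np.ndarray:
        t = np.asarray(self.t_init, dtype=float)
        if t.ndim == 0:
            return np.full(N_ZONES, float(t))
        if t.shape != (N_ZONES,):
            raise ValueError(f"t_init must be scalar or length {N_ZONES}")
        return t.copy()


@dataclass(frozen=True)
class HouseComponents:
    """Ventilation hardware of the house."""

    fan_curve: FanCurve = field(default_factory=FanCurve)
    inlets: InletRegistry = field(default_factory=InletRegistry.default)
    pad: CoolingPad = field(default_factory=CoolingPad)
    circulation: CirculationFan = field(default_factory=CirculationFan)


@dataclass
class HouseState:
    """Instantaneous state of the six-zone model."""

    time: float
    temps: np.ndarray
    dp: float = 0.0
    through_flow: np.ndarray = field(default_factory=lambda: np.zeros(N_ZONES))
    qa: np.ndarray = field(default_factory=lambda: np.zeros(N_ZONES))


@dataclass
class _Accumulators:
    """Time-integrated energy bookkeeping [J]."""

    bird: float = 0.0
    wall: float = 0.0
    advection: float = 0.0
    mixing: float = 0.0
    max_fan_residual: float = 0.0


def _bird_heat(
    config: SimulationConfig,
    bird_zone: BirdThermalParams,
    temp: float,
    v: float,
    bird_volume: float,
) -> tuple[float, float]:
    """Flock heat input to one zone [W] and the per-area flux Qa [W m-2]."""
    if config.fixed_sensible_source is not None:
        return config.fixed_sensible_source * bird_volume, 0.0
    env = EnvironmentState(ta=temp, v=v, rho=config.rho)
    if config.use_iterative_bird:
        sol = solve_bird_temperatures(bird_zone, env, tol=1e-8, max_iter=5000)
    else:
        sol = solve_bird_temperatures_direct(bird_zone, env)
    sh = sensible_heat_source(bird_zone, sol.qa)
    return sh * bird_volume, sol.qa


def step(
    state: HouseState,
    record: dict,
    config: SimulationConfig,
    layout: ZoneLayout,
    components: HouseComponents,
    bird: BirdThermalParams | None = None,
    *,
    _op: OperatingPoint | None = None,
    _inlet_matrix: np.ndarray | None = None,
    _acc: _Accumulators | None = None,
) -> HouseState:
    """Advance the house by one schedule step.

    ``record`` needs keys ``fans_on`` [count], ``fractions`` [per-inlet
    opening vector], ``t_out`` [degC] and optionally ``t_wb``.  The
    operating point sets the flow network; each zone then receives
    fresh (or pad-tempered) inflow, upstream advection, flock heat at
    its local air speed, wall conduction and circulation-fan mixing,
    integrated explicitly with automatic sub-stepping against the
    advective stability limit.
    """
    fans_on = int(record["fans_on"])
    fractions = np.asarray(record["fractions"], dtype=float)
    t_out = float(record["t_out"])
    t_wb = record.get("t_wb")

    registry = components.inlets.with_fractions(fractions)
    op = _op if _op is not None else solve_operating_point(
        fans_on, components.fan_curve, registry, components.pad, config.rho
    )
    m = _inlet_matrix if _inlet_matrix is not None else layout.inlet_matrix(registry)
    acc = _acc if _acc is not None else _Accumulators()
    acc.max_fan_residual = max(acc.max_fan_residual, op.fan_residual)

    q_fresh = (m @ op.inlet_flows) / 3600.0  # m3/s, baffle air per zone
    q_pad = np.zeros(N_ZONES)
    if op.pad_flow > 0.0:
        if t_wb is None or (isinstance(t_wb, float) and math.isnan(t_wb)):
            raise ValueError("active cooling pad requires a wet-bulb temperature")
        q_pad[list(_PAD_ZONES)] = op.pad_flow / 3600.0 / len(_PAD_ZONES)
        t_pad = cooling_pad_outlet(components.pad, t_out, float(t_wb))
    else:
        t_pad = t_out

    # Longitudinal through-flow (plug-flow chain) and local air speed.
    through = np.zeros(N_ZONES)
    for z in range(N_ZONES):
        up = _UPSTREAM[z]
        through[z] = q_fresh[z] + q_pad[z] + (through[up] if up >= 0 else 0.0)
    v_zone = through / layout.cross_section

    # Flock heat at the step's starting temperature, held across substeps.
    heat_bird = np.zeros(N_ZONES)
    qa = np.zeros(N_ZONES)
    if bird is not None or config.fixed_sensible_source is not None:
        nb_zone = (bird.nb / N_ZONES) if bird is not None else 0.0
        for z in range(N_ZONES):
            bz = (
                bird.per_zone(nb_zone, layout.bird_volume[z])
                if bird is not None and config.fixed_sensible_source is None
                else bird
            )
            heat_bird[z], qa[z] = _bird_heat(
                config, bz, state.temps[z], v_zone[z], layout.bird_volume[z]
            )

    q_mix = components.circulation.total_flow / len(_PAIRS) if fans_on == 0 else 0.0

    rho_cp = config.rho * config.cp
    cap = rho_cp * layout.air_volume  # J/K per zone
    # Advective stability limit of the explicit update.
    coef = rho_cp * (q_fresh + q_pad + np.where(
        np.array(_UPSTREAM) >= 0, through[np.maximum(_UPSTREAM, 0)], 0.0
    ) + q_mix) + config.u_wall * layout.wall_area
    with np.errstate(divide="ignore"):
        dt_stab = np.min(np.where(coef > 0, cap / np.maximum(coef, 1e-300), np.inf))
    n_sub = 1 if not np.isfinite(dt_stab) else int(
        math.ceil(config.dt / (config.substep_safety * dt_stab))
    )
    n_sub = max(n_sub, config.min_substeps, 1)
    if n_sub > config.max_substeps:
        raise RuntimeError(
            f"step at t={state.time}: {n_sub} substeps exceed the limit "
            f"(stability bound {dt_stab:.3g} s)"
        )
    h = config.dt / n_sub

    temps = state.temps.copy()
    for _ in range(n_sub):
        rhs = np.zeros(N_ZONES)
        adv = np.zeros(N_ZONES)
        for z in range(N_ZONES):
            a = rho_cp * q_fresh[z] * (t_out - temps[z])
            a += rho_cp * q_pad[z] * (t_pad - temps[z])
            up = _UPSTREAM[z]
            if up >= 0:
                a += rho_cp * through[up] * (temps[up] - temps[z])
            adv[z] = a
        wall = config.u_wall * layout.wall_area * (t_out - temps)
        mix = np.zeros(N_ZONES)
        if q_mix > 0.0:
            for i, j in _PAIRS:
                mix[i] = rho_cp * q_mix * (temps[j] - temps[i])
                mix[j] = rho_cp * q_mix * (temps[i] - temps[j])
        rhs = adv + wall + mix + heat_bird
        temps = temps + h * rhs / cap
        acc.advection += float(np.sum(adv)) * h
        acc.wall += float(np.sum(wall)) * h
        acc.mixing += float(np.sum(mix)) * h
        acc.bird += float(np.sum(heat_bird)) * h

    if not np.all(np.isfinite(temps)):
        bad = int(np.flatnonzero(~np.isfinite(temps))[0])
        raise RuntimeError(
            f"non-finite temperature in zone {ZONE_LABELS[bad]} at "
            f"t={state.time + config.dt}: adv={adv[bad]:.3g} W, "
            f"wall={wall[bad]:.3g} W, bird={heat_bird[bad]:.3g} W"
        )
    return HouseState(
        time=state.time + config.dt,
        temps=temps,
        dp=op.dp,
        through_flow=through,
        qa=qa,
    )


@dataclass
class SimulationResult:
    """Per-second trajectory of the house plus energy bookkeeping.

    ``table`` has one row per schedule record with the state at the end
    of that second: zone temperatures ``T1..T6`` [degC], through-flows
    ``F1..F6`` [m3/s], static pressure ``dp`` [Pa], total exhaust
    [m3/s] and the driving outdoor temperature.  ``audit`` carries the
    time-integrated energy terms [J] and their closure against the
    change in internal energy.
    """

    table: pd.DataFrame
    initial_temps: np.ndarray
    audit: dict

    def zone_temps(self) -> pd.DataFrame:
        return self.table[[f"T{z}" for z in ZONE_LABELS]]

    def tidy(self) -> pd.DataFrame:
        """Long-format (time, zone, temp_c, flow_m3_s) table."""
        rows = []
        for z in ZONE_LABELS:
            sub = pd.DataFrame({
                "time": self.table["time"],
                "zone": z,
                "temp_c": self.table[f"T{z}"],
                "flow_m3_s": self.table[f"F{z}"],
            })
            rows.append(sub)
        return pd.concat(rows, ignore_index=True).sort_values(
            ["time", "zone"], ignore_index=True
        )

    def to_csv(self, path) -> None:
        self.tidy().to_csv(path, index=False)


def simulate(
    schedule: Schedule,
    config: SimulationConfig | None = None,
    layout: ZoneLayout | None = None,
    components: HouseComponents | None = None,
    bird: BirdThermalParams | None = None,
) -> SimulationResult:
    """Replay a per-second schedule through the six-zone model.

    Deterministic: the same schedule and configuration always produce
    the same trajectory.  Operating points are cached per distinct
    (fans_on, opening vector) pair, which makes replaying on-off
    schedules cheap.  Schedule gaps are rejected by the
    :class:`~broilervent.schedules_io.Schedule` contract.
    """
    config = config if config is not None else SimulationConfig()
    layout = layout if layout is not None else ZoneLayout.default()
    components = components if components is not None else HouseComponents()

    fans = schedule.fans_on
    fracs = schedule.fractions
    t_out = schedule.t_out
    t_wb = schedule.t_wb
    times = schedule.frame["time"].to_numpy()

    inlet_matrix = layout.inlet_matrix(components.inlets)
    acc = _Accumulators()
    state = HouseState(time=float(times[0]), temps=config.initial_temps())
    initial = state.temps.copy()

    op_cache: dict = {}
    n = len(schedule)
    out = {
        "time": np.empty(n), "t_out": t_out.copy(), "fans_on": fans.copy(),
        "dp": np.empty(n), "exhaust_m3_s": np.empty(n),
    }
    for z in ZONE_LABELS:
        out[f"T{z}"] = np.empty(n)
        out[f"F{z}"] = np.empty(n)

    for i in range(n):
        key = (int(fans[i]), fracs[i].tobytes())
        op = op_cache.get(key)
        if op is None:
            registry = components.inlets.with_fractions(fracs[i])
            op = solve_operating_point(
                int(fans[i]), components.fan_curve, registry, components.pad,
                config.rho,
            )
            op_cache[key] = op
        record = {
            "fans_on": int(fans[i]),
            "fractions": fracs[i],
            "t_out": float(t_out[i]),
            "t_wb": float(t_wb[i]),
        }
        state = step(
            state, record, config, layout, components, bird,
            _op=op, _inlet_matrix=inlet_matrix, _acc=acc,
        )
        out["time"][i] = state.time
        out["dp"][i] = state.dp
        out["exhaust_m3_s"][i] = op.total_flow / 3600.0
        for k, z in enumerate(ZONE_LABELS):
            out[f"T{z}"][i] = state.temps[k]
            out[f"F{z}"][i] = state.through_flow[k]

    delta_e = float(np.sum(config.rho * config.cp * layout.air_volume
                           * (state.temps - initial)))
    supplied = acc.bird + acc.wall + acc.advection + acc.mixing
    audit = {
        "delta_internal_energy_J": delta_e,
        "bird_heat_J": acc.bird,
        "wall_exchange_J": acc.wall,
        "advected_enthalpy_J": acc.advection,
        "circulation_mixing_J": acc.mixing,
        "closure_residual_J": delta_e - supplied,
        "closure_relative": (delta_e - supplied) / max(abs(delta_e), 1e-300),
        "max_fan_residual_m3_h": acc.max_fan_residual,
    }
    return SimulationResult(
        table=pd.DataFrame(out), initial_temps=initial, audit=audit
    )
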