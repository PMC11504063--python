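"""Resistance-network model of broiler sensible heat exchange.

The bird is represented as three thermal layers in series — body core to
skin (tissue resistance ``rt``), skin to coat surface (coat resistance
``rc``), and coat surface to the surrounding air (boundary-layer
resistance ``ra``) — with parallel paths for conduction to the floor
through the non-exposed body fraction, long-wave radiation to the
surroundings, and latent losses from the skin (``Ec``) and the
respiratory tract (``Er``).  The body core is held at a fixed deep-body
temperature; the skin and coat-surface temperatures adjust so that the
layer fluxes balance:

    Qt   = (Tb - Ts) / rt                       core -> skin
    Qc   = (Ts - Tc) / rc + Ec                  skin -> coat surface
    Qa   = (Tc - Ta) / ra                       coat -> air (convection)
    Qflr = (Ts - Tflr) / (rt + rflr)            contact conduction
    Qr   = (Tc - Tr) / rr                       long-wave radiation

closed by the two balance conditions

    Qt = R*Qc + Er + (1 - R)*Qflr               (core balance)
    Qc = Qa + Qr                                (coat-surface balance)

where ``R`` is the fraction of body surface exposed to air.  ``Qa`` is
the sensible heat the flock delivers to the house air; scaled by bird
surface area, head count and bird-zone volume it becomes the volumetric
source term used by the zonal simulator.  The flock also acts as a drag
obstacle, removing momentum from the near-floor flow.

Two solvers are provided: the fixed-point iteration (with adaptive
under-relaxation, since the plain iteration can oscillate for realistic
resistance values) and a closed-form solution of the equivalent 2x2
linear system, which serves as the algebraic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Union

__all__ = [
    "BirdThermalParams",
    "EnvironmentState",
    "BirdThermalSolution",
    "mixed_convection_resistance",
    "initial_temperatures",
    "solve_bird_temperatures",
    "solve_bird_temperatures_direct",
    "sensible_heat_source",
    "drag_momentum_sink",
]

#: Boundary-layer resistance may be a constant [m2 degC/W] or a function of
#: local air speed [m/s] returning the resistance.
ResistanceLike = Union[float, Callable[[float], float]]


def mixed_convection_resistance(
    h_natural: float = 4.2, a: float = 9.0, b: float = 0.6
) -> Callable[[float], float]:
    """Boundary-layer resistance as a function of air speed.

    Convective coefficient ``h = h_natural + a * v**b`` [W m-2 K-1]: a
    natural-convection floor plus a forced-convection power law of the
    local air speed, the usual shape for bluff animal bodies.  Returns
    ``ra(v) = 1/h``.
    """
    if h_natural <= 0:
        raise ValueError("h_natural must be > 0")

    def ra(v: float) -> float:
        return 1.0 / (h_natural + a * max(v, 0.0) ** b)

    return ra


@dataclass(frozen=True)
class BirdThermalParams:
    """Physiological and geometric constants of the flock heat model.

    Resistances are in m2 degC W-1, temperatures in degC, areas in m2,
    fluxes in W m-2.  The resistance/latent values are configuration:
    the defaults are documented placeholders of the right order of
    magnitude for 3-week broilers, not measured constants.

    tb : deep-body (core) temperature, held constant during a solve.
    rt, rc, rflr, rr : tissue, coat, floor-contact and radiative
        resistances.
    ra : boundary-layer resistance; a constant or a callable of air
        speed (see :func:`mixed_convection_resistance`, the default).
    ec : latent heat loss from the skin surface.
    er : respiratory latent heat loss (core -> air, bypassing the skin).
    exposed : fraction R of the body surface exposed to air, in [0, 1];
        the remainder is in contact with the floor.
    ac : bird surface area.  ap : projected (frontal) area.
    cd : drag coefficient.  nb : number of birds.  vz : bird-zone
        air volume [m3] the flock occupies.
    """

    tb: float = 41.0
    rt: float = 0.10
    rc: float = 0.15
    ra: ResistanceLike = field(default_factory=mixed_convection_resistance)
    rflr: float = 0.30
    rr: float = 0.18
    ec: float = 10.0
    er: float = 5.0
    exposed: float = 0.8
    ac: float = 0.1
    ap: float = 0.05
    cd: float = 1.0
    nb: float = 30_000
    vz: float = 587.25

    def __post_init__(self) -> None:
        for name in ("rt", "rc", "rflr", "rr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"resistance {name} must be > 0")
        if not callable(self.ra) and self.ra <= 0:
            raise ValueError("resistance ra must be > 0")
        if not 0.0 <= self.exposed <= 1.0:
            raise ValueError("exposed fraction must be in [0, 1]")
        for name in ("ac", "ap", "vz", "nb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def ra_at(self, v: float) -> float:
        """Boundary-layer resistance at air speed ``v`` [m/s]."""
        r = self.ra(v) if callable(self.ra) else float(self.ra)
        if r <= 0 or not math.isfinite(r):
            raise ValueError(f"ra({v}) = {r} is not a positive finite resistance")
        return r

    def per_zone(self, nb: float, vz: float) -> "BirdThermalParams":
        """Copy with flock size and bird-zone volume for one house zone."""
        return replace(self, nb=nb, vz=vz)


@dataclass(frozen=True)
class EnvironmentState:
    """Local environment around the birds.

    ta : air temperature [degC]; tflr, tr : floor and mean-radiant
    temperatures [degC], defaulting to ``ta`` when not supplied;
    v : local air speed [m/s]; rho : air density [kg/m3].
    """

    ta: float
    tflr: float | None = None
    tr: float | None = None
    v: float = 0.0
    rho: float = 1.2

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("air speed v must be >= 0")
        if self.rho <= 0:
            raise ValueError("air density rho must be > 0")

    @property
    def floor_temp(self) -> float:
        return self.ta if self.tflr is None else self.tflr

    @property
    def radiant_temp(self) -> float:
        return self.ta if self.tr is None else self.tr


@dataclass(frozen=True)
class BirdThermalSolution:
    """Converged skin/coat temperatures and the associated fluxes."""

    ts: float
    tc: float
    qt: float
    qc: float
    qa: float
    qflr: float
    qr: float
    iterations: int
    converged: bool
    residual: float = 0.0

    def balance_residuals(
        self, params: BirdThermalParams, env: EnvironmentState,
        respiration_exposed: bool = False,
    ) -> tuple[float, float]:
        """Residuals of the two balance conditions at this solution [W m-2]."""
        er_coef = params.exposed if respiration_exposed else 1.0
        r1 = self.qt - (
            params.exposed * self.qc + er_coef * params.er
            + (1.0 - params.exposed) * self.qflr
        )
        r2 = self.qc - (self.qa + self.qr)
        return r1, r2


def initial_temperatures(tb: float, ta: float) -> tuple[float, float]:
    """Starting skin/coat temperatures for the fixed-point iteration.

    The core-to-air temperature difference is split into three equal
    parts: skin one third below the core, coat surface two thirds below.
    """
    d = (tb - ta) / 3.0
    return tb - d, tb - 2.0 * d


def _fluxes(
    params: BirdThermalParams, env: EnvironmentState, ts: float, tc: float,
    ra: float,
) -> tuple[float, float, float, float, float]:
    qt = (params.tb - ts) / params.rt
    qc = (ts - tc) / params.rc + params.ec
    qa = (tc - env.ta) / ra
    qflr = (ts - env.floor_temp) / (params.rt + params.rflr)
    qr = (tc - env.radiant_temp) / params.rr
    return qt, qc, qa, qflr, qr


def solve_bird_temperatures(
    params: BirdThermalParams,
    env: EnvironmentState,
    tol: float = 1e-6,
    max_iter: int = 1000,
    damping: float = 1.0,
    respiration_exposed: bool = False,
) -> BirdThermalSolution:
    """Fixed-point solution of the skin/coat temperature balance.

    Starting from :func:`initial_temperatures`, each sweep evaluates the
    coat-surface balance ``Qc = Qa + Qr`` and the core balance for
    ``Qt`` at the current temperatures, then updates ``Ts`` from the
    tissue layer and ``Tc`` from the coat layer; the sweep repeats until
    both temperature updates fall below ``tol`` [degC].

    The plain sweep (``damping=1``) can oscillate or diverge when the
    coat and boundary-layer resistances are small relative to the
    tissue resistance.  The iteration therefore adapts its relaxation
    factor from the correlation ratio ``r`` of successive raw updates
    (an estimate of the dominant eigenvalue of the relaxed sweep): on
    oscillation or growth the factor is reset to ``omega/(1 - r)``,
    the value that would annihilate the offending mode.  This changes
    only the path to the fixed point, never the fixed point itself.

    ``respiration_exposed`` selects the alternative core-balance
    grouping ``Qt = R*(Qc + Er) + (1-R)*Qflr`` in which respiration
    scales with the exposed fraction; the default counts the full
    respiratory loss against the core.

    Non-convergence within ``max_iter`` returns a flagged result
    (``converged=False``) carrying the last residual, never raises.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 < damping <= 1:
        raise ValueError("damping must be in (0, 1]")

    ra = params.ra_at(env.v)
    er_coef = params.exposed if respiration_exposed else 1.0
    r_exp = params.exposed
    ts, tc = initial_temperatures(params.tb, env.ta)
    omega = damping
    d_prev: tuple[float, float] | None = None
    iterations = 0
    res = 0.0
    converged = False
    for iterations in range(1, max_iter + 1):
        qc = (tc - env.ta) / ra + (tc - env.radiant_temp) / params.rr
        qflr = (ts - env.floor_temp) / (params.rt + params.rflr)
        qt = r_exp * qc + er_coef * params.er + (1.0 - r_exp) * qflr
        ts_new = params.tb - params.rt * qt
        tc_new = ts_new - params.rc * (qc - params.ec)
        dts, dtc = ts_new - ts, tc_new - tc
        res = max(abs(dts), abs(dtc))
        if res < tol:
            ts, tc = ts_new, tc_new
            converged = True
            break
        if d_prev is not None:
            norm = d_prev[0] ** 2 + d_prev[1] ** 2
            if norm > 0.0:
                # dominant-eigenvalue estimate of the relaxed sweep
                r = (dts * d_prev[0] + dtc * d_prev[1]) / norm
                if r < 0.0:
                    omega = min(damping, max(omega / (1.0 - r), 1e-8))
                elif r >= 1.0:
                    omega = max(omega * 0.5, 1e-8)
        ts += omega * dts
        tc += omega * dtc
        d_prev = (dts, dtc)

    qt, qc, qa, qflr, qr = _fluxes(params, env, ts, tc, ra)
    return BirdThermalSolution(
        ts=ts, tc=tc, qt=qt, qc=qc, qa=qa, qflr=qflr, qr=qr,
        iterations=iterations, converged=converged, residual=res,
    )


def solve_bird_temperatures_direct(
    params: BirdThermalParams,
    env: EnvironmentState,
    respiration_exposed: bool = False,
) -> BirdThermalSolution:
    """Closed-form solution of the skin/coat balance.

    With constant latent terms the five flux laws substituted into the
    two balance conditions form a linear 2x2 system in ``(Ts, Tc)``;
    this solves it exactly and is the oracle against which the
    fixed-point scheme is verified.
    """
    ra = params.ra_at(env.v)
    a1 = 1.0 / params.rt
    aflr = 1.0 / (params.rt + params.rflr)
    b = 1.0 / params.rc
    c = 1.0 / ra + 1.0 / params.rr
    d = env.ta / ra + env.radiant_temp / params.rr
    r_exp = params.exposed
    er_coef = params.exposed if respiration_exposed else 1.0

    k = a1 + (1.0 - r_exp) * aflr
    m = (
        a1 * params.tb + r_exp * d - er_coef * params.er
        + (1.0 - r_exp) * aflr * env.floor_temp
    )
    denom = k * (b + c) + b * r_exp * c
    if abs(denom) < 1e-300:
        raise ValueError("degenerate resistance combination: singular balance system")
    tc = (b * m + k * (d + params.ec)) / denom
    ts = ((b + c) * tc - d - params.ec) / b

    qt, qc, qa, qflr, qr = _fluxes(params, env, ts, tc, ra)
    return BirdThermalSolution(
        ts=ts, tc=tc, qt=qt, qc=qc, qa=qa, qflr=qflr, qr=qr,
        iterations=0, converged=True, residual=0.0,
    )


def sensible_heat_source(params: BirdThermalParams, qa: float) -> float:
    """Volumetric sensible-heat source of the flock [W m-3].

    ``Sh = Ac * nb * Qa / Vz``: the per-area convective flux scaled by
    bird surface area and head count, spread over the bird-zone volume.
    """
    if not math.isfinite(qa):
        raise ValueError("qa must be finite")
    return params.ac * params.nb * qa / params.vz


def drag_momentum_sink(params: BirdThermalParams, env: EnvironmentState) -> float:
    """Volumetric momentum sink of the flock [kg m-2 s-2].

    ``Su = -(nb * Ap * Cd / Vz) * rho * v**2 / 2``: quadratic drag of
    the birds on the near-floor airflow, always <= 0.
    """
    return -(params.nb * params.ap * params.cd / params.vz) * 0.5 * env.rho * env.v**2
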