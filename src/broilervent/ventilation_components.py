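"""Lumped component models of the tunnel-ventilation system.

Exhaust fans, side-wall inlet baffles, evaporative cooling pads and
ceiling circulation fans, plus the building static-pressure operating
point that couples them: the fans demand less air as the indoor/outdoor
pressure difference grows, while the pressure difference drives more
air in through whatever openings are available.  The operating point is
the pressure at which demand and supply balance, and it determines both
the total ventilation rate and how the incoming air splits between the
individual inlets and the pads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FanCurve",
    "InletRegistry",
    "CoolingPad",
    "CirculationFan",
    "OperatingPoint",
    "fan_flow",
    "inlet_flow",
    "baffle_momentum_sink",
    "cooling_pad_outlet",
    "solve_operating_point",
]

SECTIONS = ("far", "mid", "near")


@dataclass(frozen=True)
class FanCurve:
    """Affine exhaust-fan performance curve.

    ``Q(dP) = max(0, q0 - k*dP)`` [m3/h] against static pressure dP
    [Pa]; ``at`` is the fan opening area [m2] used to convert flow to
    face velocity.  Default free-air capacity brackets the rated
    37,000 m3/h of the reference house fans.
    """

    q0: float = 38_650.0
    k: float = 588.0
    at: float = 1.47

    def __post_init__(self) -> None:
        if self.q0 <= 0:
            raise ValueError("free-air capacity q0 must be > 0")
        if self.k < 0:
            raise ValueError("pressure-loss slope k must be >= 0")
        if self.at <= 0:
            raise ValueError("fan area at must be > 0")

    @property
    def cutoff_pressure(self) -> float:
        """Pressure [Pa] at which delivery reaches zero (inf if k == 0)."""
        return self.q0 / self.k if self.k > 0 else math.inf


def fan_flow(curve: FanCurve, dp: float) -> tuple[float, float]:
    """Flow [m3/h] and face velocity [m/s] of one fan at pressure ``dp``.

    Monotone non-increasing in ``dp``, clamped at zero.
    """
    if dp < 0:
        raise ValueError("static pressure dp must be >= 0")
    q = max(0.0, curve.q0 - curve.k * dp)
    return q, q / (3600.0 * curve.at)


def _default_sections(n: int = 29) -> list[str]:
    # 10/9/10 far/mid/near: equal far and near areas make the +-50%
    # scenario swap conserve total open area exactly.
    n_far = (n + 1) // 3
    n_near = n_far
    n_mid = n - n_far - n_near
    return ["far"] * n_far + ["mid"] * n_mid + ["near"] * n_near


@dataclass(frozen=True)
class InletRegistry:
    """Side-wall inlet baffles: geometry, grouping and current openings.

    Each inlet has a geometric opening area [m2], a side label
    (``L``/``R``), a longitudinal section label (``far``/``mid``/
    ``near``, counted from the end wall opposite the fans), and a
    time-varying opening fraction in [0, 1].  A sharp-edged-orifice
    discharge coefficient converts pressure difference to flow; a fully
    closed inlet passes no flow at any pressure.
    """

    areas: np.ndarray
    sides: tuple[str, ...]
    sections: tuple[str, ...]
    fractions: np.ndarray
    ids: tuple[str, ...]
    cd: float = 0.61

    def __post_init__(self) -> None:
        n = len(self.areas)
        if not (len(self.sides) == len(self.sections) == len(self.fractions)
                == len(self.ids) == n):
            raise ValueError("inlet attribute lengths disagree")
        if np.any(self.areas <= 0):
            raise ValueError("inlet areas must be > 0")
        if not 0 < self.cd <= 1:
            raise ValueError("discharge coefficient must be in (0, 1]")
        bad = set(self.sections) - set(SECTIONS)
        if bad:
            raise ValueError(f"unknown section labels: {sorted(bad)}")
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        object.__setattr__(
            self, "fractions", np.clip(np.asarray(self.fractions, dtype=float), 0.0, 1.0)
        )

    @classmethod
    def default(
        cls, n_per_side: int = 29, area: float = 0.3, cd: float = 0.61,
        fraction: float = 1.0,
    ) -> "InletRegistry":
        """Registry of the reference house: 29 uniform inlets per side."""
        sections = _default_sections(n_per_side)
        sides: list[str] = []
        secs: list[str] = []
        ids: list[str] = []
        for side in ("L", "R"):
            for i, sec in enumerate(sections, start=1):
                sides.append(side)
                secs.append(sec)
                ids.append(f"{side}{i:02d}")
        n = 2 * n_per_side
        return cls(
            areas=np.full(n, area),
            sides=tuple(sides),
            sections=tuple(secs),
            fractions=np.full(n, float(fraction)),
            ids=tuple(ids),
            cd=cd,
        )

    def __len__(self) -> int:
        return len(self.areas)

    def with_fractions(self, fractions: Sequence[float]) -> "InletRegistry":
        f = np.asarray(fractions, dtype=float)
        if f.shape != self.areas.shape:
            raise ValueError("fraction vector length mismatch")
        return replace(self, fractions=f)

    def effective_area(self) -> float:
        """Total open area [m2] at the current fractions."""
        return float(np.sum(self.areas * self.fractions))

    def section_mask(self, section: str) -> np.ndarray:
        if section not in SECTIONS:
            raise ValueError(f"unknown section {section!r}")
        return np.array([s == section for s in self.sections])


def inlet_flow(registry: InletRegistry, dp: float, rho: float = 1.2) -> np.ndarray:
    """Per-inlet volumetric flow [m3/h] at static pressure ``dp`` [Pa].

    Orifice closure: ``Q_i = cd * A_i * f_i * sqrt(2*dp/rho) * 3600``.
    A closed inlet (f_i = 0) passes zero flow regardless of pressure —
    the lumped counterpart of blocking the closed baffle area.
    """
    if dp < 0:
        raise ValueError("static pressure dp must be >= 0")
    if rho <= 0:
        raise ValueError("air density rho must be > 0")
    v = math.sqrt(2.0 * dp / rho)
    return registry.cd * registry.areas * registry.fractions * v * 3600.0


def baffle_momentum_sink(rho: float, v: float, dt: float) -> float:
    """Momentum sink applied to closed baffle area [kg m-2 s-2].

    ``Su_inlet = -rho*v/dt``: the field-scale (CFD-facing) form that
    cancels the local momentum within one time step.  The zonal
    surrogate realizes the same contract through the orifice closure in
    :func:`inlet_flow`; this form is retained for documentation and
    testing of the blocking term itself.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return -rho * v / dt


@dataclass(frozen=True)
class CoolingPad:
    """Evaporative cooling pad on the side walls.

    Air drawn through the wetted pad is cooled by ``efficiency`` of the
    dry-bulb/wet-bulb depression.  Airflow resistance is the porous
    inertial coefficient [1/m] over the pad thickness [m], converted to
    an equivalent-orifice law for the lumped pressure balance:
    ``v_face = sqrt(2*dp / (rho * resistance * thickness))``.
    """

    face_area: float = 48.0
    inertial_resistance: float = 23.3
    thickness: float = 0.15
    efficiency: float = 0.7
    active: bool = False

    def __post_init__(self) -> None:
        if self.face_area <= 0 or self.thickness <= 0 or self.inertial_resistance <= 0:
            raise ValueError("pad geometry/resistance must be > 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("saturation efficiency must be in [0, 1]")

    def flow(self, dp: float, rho: float = 1.2) -> float:
        """Pad airflow [m3/h] at pressure ``dp`` [Pa]; zero when inactive."""
        if dp < 0:
            raise ValueError("static pressure dp must be >= 0")
        if not self.active:
            return 0.0
        v = math.sqrt(2.0 * dp / (rho * self.inertial_resistance * self.thickness))
        return self.face_area * v * 3600.0


def cooling_pad_outlet(pad: CoolingPad, tdb: float, twb: float) -> float:
    """Air temperature [degC] downstream of the pad.

    ``Tout = Tdb - efficiency*(Tdb - Twb)``; an inactive pad passes the
    air through unchanged.
    """
    if twb > tdb:
        raise ValueError("wet-bulb temperature cannot exceed dry-bulb")
    if not pad.active:
        return tdb
    return tdb - pad.efficiency * (tdb - twb)


@dataclass(frozen=True)
class CirculationFan:
    """Ceiling circulation fans used while the tunnel fans are off.

    Each fan pulls air upward through its intake at a constant speed
    and disperses it radially; the zonal surrogate books this as a
    mixing exchange between laterally paired zones.
    """

    intake_speed: float = 4.4
    count: int = 6
    intake_area: float = 0.196

    def __post_init__(self) -> None:
        if self.intake_speed < 0:
            raise ValueError("intake speed must be >= 0")
        if self.count < 0 or self.intake_area <= 0:
            raise ValueError("count must be >= 0 and intake area > 0")

    @property
    def total_flow(self) -> float:
        """Total recirculated flow [m3/s]."""
        return self.intake_speed * self.intake_area * self.count


@dataclass(frozen=True)
class OperatingPoint:
    """Mass-consistent flow solution of the ventilation network.

    dp : static pressure difference [Pa]; total_flow : total supply
    (== exhaust) [m3/h]; inlet_flows : per-inlet flows [m3/h];
    pad_flow [m3/h]; fan_residual : |fan demand - supply| [m3/h] at dp;
    clamped : True when no balancing pressure exists (e.g. fans running
    against a sealed house) and the boundary solution is returned.
    """

    dp: float
    total_flow: float
    inlet_flows: np.ndarray
    pad_flow: float
    fan_residual: float
    clamped: bool = False


def solve_operating_point(
    fans_on: int,
    curve: FanCurve,
    registry: InletRegistry,
    pad: CoolingPad | None = None,
    rho: float = 1.2,
) -> OperatingPoint:
    """Static-pressure operating point of the house.

    Finds ``dp >= 0`` such that total fan demand ``fans_on * Q(dp)``
    equals the pressure-driven supply through open inlets and (when
    active) the cooling pads, by bracketing and Brent root finding.
    The returned flows are the supply flows at that pressure, so the
    flow set is mass-consistent by construction; ``fan_residual``
    reports the (tiny) demand/supply mismatch left by the root finder.

    With all openings closed and fans running there is no balancing
    pressure: the fan cutoff pressure and zero flows are returned with
    ``clamped=True``.
    """
    if fans_on < 0:
        raise ValueError("fans_on must be >= 0")
    if rho <= 0:
        raise ValueError("air density rho must be > 0")
    n = len(registry)
    if fans_on == 0:
        return OperatingPoint(0.0, 0.0, np.zeros(n), 0.0, 0.0, False)

    pad = pad if pad is not None else CoolingPad(active=False)

    def supply(dp: float) -> float:
        return float(np.sum(inlet_flow(registry, dp, rho))) + pad.flow(dp, rho)

    def residual(dp: float) -> float:
        return fans_on * fan_flow(curve, dp)[0] - supply(dp)

    open_area = registry.effective_area() + (pad.face_area if pad.active else 0.0)
    if open_area <= 1e-12:
        dp = curve.cutoff_pressure if math.isfinite(curve.cutoff_pressure) else 1e6
        return OperatingPoint(
            dp, 0.0, np.zeros(n), 0.0, fans_on * fan_flow(curve, dp)[0], True
        )

    hi = curve.cutoff_pressure
    if not math.isfinite(hi):
        hi = 1.0
        while residual(hi) > 0.0:
            hi *= 2.0
    # residual(0) = fans_on*q0 > 0 and residual(hi) <= 0: root bracketed.
    dp = brentq(residual, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    flows = inlet_flow(registry, dp, rho)
    pad_q = pad.flow(dp, rho)
    total = float(np.sum(flows)) + pad_q
    return OperatingPoint(dp, total, flows, pad_q, abs(residual(dp)), False)
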