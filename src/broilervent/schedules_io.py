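"""Operational schedules: log ingestion, synthesis and inlet scenarios.

The farm controller logs state changes (number of tunnel fans running,
baffle openings, outdoor conditions) as timestamped JSON events.  The
simulator consumes a dense per-second schedule, so events are
forward-filled onto a 1-second grid: a logged change applies from its
own timestamp (inclusive).  A synthetic generator produces the on-off
duty-cycle schedules typical of mild-weather operation, and the
scenario transform rescales inlet openings by longitudinal section
(far/mid/near of the tunnel-fan wall) while conserving total open
area — the variable-inlet strategies for thermal-gradient control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ventilation_components import SECTIONS, InletRegistry

__all__ = [
    "Schedule",
    "ScenarioSpec",
    "CASE_1",
    "CASE_2",
    "parse_operational_log",
    "synth_schedule",
    "apply_scenario",
]

MAX_FANS = 14

_META_COLUMNS = ("time", "fans_on", "t_out", "t_wb")


@dataclass(frozen=True)
class Schedule:
    """Dense per-second operational record.

    ``frame`` columns: ``time`` [s, contiguous integers], ``fans_on``
    [0..installed], ``t_out`` / ``t_wb`` [degC, wet-bulb may be NaN],
    and one opening-fraction column ``f_<inlet id>`` per inlet, each in
    [0, 1].
    """

    frame: pd.DataFrame
    inlet_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.frame
        for col in _META_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"schedule is missing column {col!r}")
        missing = [i for i in self.inlet_ids if f"f_{i}" not in df.columns]
        if missing:
            raise ValueError(f"schedule is missing fraction columns for {missing}")
        t = df["time"].to_numpy()
        if len(t) == 0:
            raise ValueError("empty schedule")
        if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValueError("schedule must be gap-free at 1-second spacing")
        fans = df["fans_on"].to_numpy()
        if np.any(fans < 0) or np.any(fans > MAX_FANS):
            raise ValueError(f"fans_on must lie in [0, {MAX_FANS}]")
        f = self.fractions
        if np.any(f < -1e-12) or np.any(f > 1.0 + 1e-12):
            raise ValueError("opening fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def fraction_columns(self) -> list[str]:
        return [f"f_{i}" for i in self.inlet_ids]

    @property
    def fractions(self) -> np.ndarray:
        """(n_steps, n_inlets) opening-fraction matrix."""
        return self.frame[self.fraction_columns].to_numpy(dtype=float)

    @property
    def fans_on(self) -> np.ndarray:
        return self.frame["fans_on"].to_numpy(dtype=int)

    @property
    def t_out(self) -> np.ndarray:
        return self.frame["t_out"].to_numpy(dtype=float)

    @property
    def t_wb(self) -> np.ndarray:
        return self.frame["t_wb"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Schedule":
        df = pd.read_csv(path, float_precision="round_trip")
        ids = tuple(c[2:] for c in df.columns if c.startswith("f_"))
        return cls(frame=df, inlet_ids=ids)

    def on_off_intervals(self) -> list[tuple[int, int, bool]]:
        """Maximal constant-ventilation runs as (start, end, fans_running).

        ``end`` is exclusive; ``fans_running`` is True when fans_on > 0
        throughout the run.
        """
        on = self.fans_on > 0
        edges = np.flatnonzero(np.diff(on.astype(int))) + 1
        bounds = [0, *edges.tolist(), len(on)]
        return [(a, b, bool(on[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def _expand_baffles(
    value: object, registry: InletRegistry, where: str
) -> np.ndarray:
    """Expand a scalar / per-section / per-inlet baffle spec to a vector."""
    n = len(registry)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return np.full(n, float(value))
    if isinstance(value, Mapping):
        keys = set(value)
        if keys <= set(SECTIONS):
            out = np.full(n, np.nan)
            for sec, f in value.items():
                out[registry.section_mask(sec)] = float(f)
            if np.isnan(out).any():
                raise ValueError(f"{where}: per-section baffles must cover all sections")
            return out
        if keys <= set(registry.ids):
            if keys != set(registry.ids):
                raise ValueError(f"{where}: per-inlet baffles must cover every inlet")
            return np.array([float(value[i]) for i in registry.ids])
        raise ValueError(
            f"{where}: baffle keys must all be sections {SECTIONS} or inlet ids"
        )
    raise ValueError(f"{where}: baffles must be a number or a mapping")


_EVENT_FIELDS = {"t", "fans_on", "baffles", "t_out", "t_wb"}


def parse_operational_log(
    source: str | Path | Mapping,
    registry: InletRegistry | None = None,
    end: int | None = None,
) -> Schedule:
    """Ingest a JSON controller log into a per-second :class:`Schedule`.

    The log is ``{"end": <s>, "events": [{"t": <s>, ...}, ...]}`` where
    each event may set ``fans_on``, ``baffles`` (a scalar fraction, a
    per-section mapping, or a per-inlet mapping) and ``t_out`` /
    ``t_wb``.  Events apply from their own timestamp (inclusive) and
    hold until the next change.  The first event must define the full
    state.  Out-of-order timestamps and unknown fields are rejected.
    """
    registry = registry if registry is not None else InletRegistry.default()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)

    unknown = set(doc) - {"end", "events"}
    if unknown:
        raise ValueError(f"unknown top-level fields in log: {sorted(unknown)}")
    events = doc.get("events")
    if not events:
        raise ValueError("log contains no events")
    horizon_end = end if end is not None else doc.get("end")
    if horizon_end is None:
        raise ValueError("log must declare 'end' (seconds) or pass end=")

    prev_t = None
    for i, ev in enumerate(events):
        unknown = set(ev) - _EVENT_FIELDS
        if unknown:
            raise ValueError(f"event {i}: unknown fields {sorted(unknown)}")
        if "t" not in ev:
            raise ValueError(f"event {i}: missing timestamp 't'")
        if prev_t is not None and ev["t"] < prev_t:
            raise ValueError(
                f"event {i}: out-of-order timestamp {ev['t']} after {prev_t}"
            )
        prev_t = ev["t"]

    first = events[0]
    for req in ("fans_on", "baffles", "t_out"):
        if req not in first:
            raise ValueError(f"first event must define {req!r}")

    start = int(first["t"])
    n = int(horizon_end) - start
    if n <= 0:
        raise ValueError("log horizon is empty")

    fans = np.zeros(n, dtype=int)
    t_out = np.zeros(n)
    t_wb = np.full(n, np.nan)
    fracs = np.zeros((n, len(registry)))

    state_fans = int(first["fans_on"])
    state_frac = _expand_baffles(first["baffles"], registry, "event 0")
    state_tout = float(first["t_out"])
    state_twb = float(first["t_wb"]) if first.get("t_wb") is not None else np.nan

    ev_iter = iter(events[1:])
    nxt = next(ev_iter, None)
    for t in range(start, start + n):
        while nxt is not None and nxt["t"] <= t:
            if "fans_on" in nxt:
                state_fans = int(nxt["fans_on"])
            if "baffles" in nxt:
                state_frac = _expand_baffles(nxt["baffles"], registry, f"t={nxt['t']}")
            if "t_out" in nxt:
                state_tout = float(nxt["t_out"])
            if "t_wb" in nxt:
                state_twb = float(nxt["t_wb"]) if nxt["t_wb"] is not None else np.nan
            nxt = next(ev_iter, None)
        i = t - start
        fans[i] = state_fans
        t_out[i] = state_tout
        t_wb[i] = state_twb
        fracs[i] = state_frac

    return _assemble(start, fans, t_out, t_wb, fracs, registry)


def _assemble(
    start: int,
    fans: np.ndarray,
    t_out: np.ndarray,
    t_wb: np.ndarray,
    fracs: np.ndarray,
    registry: InletRegistry,
) -> Schedule:
    n = len(fans)
    data = {
        "time": np.arange(start, start + n),
        "fans_on": fans,
        "t_out": t_out,
        "t_wb": t_wb,
    }
    for j, inlet_id in enumerate(registry.ids):
        data[f"f_{inlet_id}"] = fracs[:, j]
    return Schedule(frame=pd.DataFrame(data), inlet_ids=tuple(registry.ids))


def synth_schedule(
    horizon_s: int = 3600,
    period_s: int = 300,
    duty: float = 0.2,
    fans_when_on: int = 5,
    baffle_open: float = 0.6,
    baffle_closed: float = 0.0,
    t_out_start: float = 14.8,
    t_out_end: float = 12.7,
    t_wb: float | None = None,
    registry: InletRegistry | None = None,
    seed: int | None = None,
    period_jitter: float = 0.0,
) -> Schedule:
    """Synthetic on-off ventilation schedule.

    Emulates mild-weather thermostatic operation: each ``period_s``
    cycle starts with ``duty`` of the period in the fan-on state
    (baffles at ``baffle_open``), then fans off (baffles at
    ``baffle_closed``), while the outdoor temperature drifts linearly
    from ``t_out_start`` to ``t_out_end`` across the horizon.  With
    ``period_jitter > 0`` the on-duration of each cycle is perturbed by
    a seeded uniform factor in ``1 +- period_jitter``, emulating the
    irregular run lengths of a real thermostat; the series is fully
    reproducible for a given seed.
    """
    if horizon_s <= 0:
        raise ValueError("horizon_s must be > 0")
    if period_s <= 0:
        raise ValueError("degenerate duty cycle: period_s must be > 0")
    if not 0.0 <= duty <= 1.0:
        raise ValueError("degenerate duty cycle: duty must be in [0, 1]")
    if not 0 <= fans_when_on <= MAX_FANS:
        raise ValueError(f"fans_when_on must be in [0, {MAX_FANS}]")
    if not 0.0 <= period_jitter < 1.0:
        raise ValueError("period_jitter must be in [0, 1)")

    registry = registry if registry is not None else InletRegistry.default()
    rng = np.random.default_rng(seed)
    on = np.zeros(horizon_s, dtype=bool)
    base_on = int(round(duty * period_s))
    for start in range(0, horizon_s, period_s):
        on_len = base_on
        if period_jitter > 0.0:
            on_len = int(round(base_on * (1.0 + rng.uniform(-period_jitter, period_jitter))))
        on_len = min(max(on_len, 0), period_s)
        on[start : min(start + on_len, horizon_s)] = True

    fans = np.where(on, fans_when_on, 0).astype(int)
    fracs = np.where(on[:, None], baffle_open, baffle_closed) * np.ones(
        (horizon_s, len(registry))
    )
    t_out = np.linspace(t_out_start, t_out_end, horizon_s)
    twb = np.full(horizon_s, np.nan if t_wb is None else float(t_wb))
    return _assemble(0, fans, t_out, twb, fracs, registry)


@dataclass(frozen=True)
class ScenarioSpec:
    """Section-wise inlet-opening multipliers (far, mid, near).

    ``conserve_total`` asserts that the transform leaves the total open
    area unchanged at every time step (the design constraint of the
    variable-inlet strategies); a violated constraint is an error.
    """

    multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    conserve_total: bool = True

    def __post_init__(self) -> None:
        if len(self.multipliers) != 3:
            raise ValueError("multipliers must be (far, mid, near)")
        if any(m < 0 for m in self.multipliers):
            raise ValueError("multipliers must be >= 0")


#: Less open at the far end, more open near the fans.
CASE_1 = ScenarioSpec((0.5, 1.0, 1.5))
#: More open at the far end, less open near the fans.
CASE_2 = ScenarioSpec((1.5, 1.0, 0.5))


def apply_scenario(
    schedule: Schedule,
    spec: ScenarioSpec,
    registry: InletRegistry | None = None,
) -> Schedule:
    """Rescale per-section opening areas of a schedule.

    Every inlet's opening fraction is multiplied by its section's
    multiplier; scaled fractions must stay within [0, 1] (an opening
    cannot exceed fully open).  When ``spec.conserve_total`` is set,
    the effective open area ``sum(A_i * f_i)`` must match the baseline
    at every time step to 1e-9 relative, else the transform is rejected
    with the worst residual.
    """
    registry = registry if registry is not None else InletRegistry.default()
    if tuple(registry.ids) != schedule.inlet_ids:
        raise ValueError("registry inlet ids do not match the schedule")
    mult = np.empty(len(registry))
    for sec, m in zip(SECTIONS, spec.multipliers):
        mult[registry.section_mask(sec)] = m

    base = schedule.fractions
    scaled = base * mult[None, :]
    if np.any(scaled > 1.0 + 1e-12):
        worst = float(scaled.max())
        raise ValueError(
            f"scenario drives an opening fraction to {worst:.3f} > 1; "
            "openings cannot exceed fully open"
        )
    if spec.conserve_total:
        a = registry.areas
        tot_base = base @ a
        tot_scaled = scaled @ a
        denom = np.maximum(np.abs(tot_base), 1e-300)
        rel = np.abs(tot_scaled - tot_base) / denom
        nonzero = tot_base > 0
        if np.any(rel[nonzero] > 1e-9):
            raise ValueError(
                "scenario violates open-area conservation: max relative "
                f"residual {float(rel[nonzero].max()):.3e}"
            )

    df = schedule.frame.copy()
    for j, inlet_id in enumerate(schedule.inlet_ids):
        df[f"f_{inlet_id}"] = scaled[:, j]
    return Schedule(frame=df, inlet_ids=schedule.inlet_ids)
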