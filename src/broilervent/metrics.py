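"""Validation metrics for measured-vs-simulated comparisons.

Small, exact arithmetic on paired comparison tables: signed errors and
their extremes for point measurements (air velocity at zone centres),
total-airflow agreement percentages, RMSE for temperature time series,
and the longitudinal thermal-gradient metric (near-fan minus far-end
zone temperatures) used to judge variable-inlet strategies.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "load_comparison_table",
    "load_fixture",
    "list_fixtures",
    "signed_errors",
    "agreement_percent",
    "rmse",
    "gradient_metric",
]

_REQUIRED = ("location", "measured", "simulated", "units")

#: Packaged measured-vs-simulated validation tables of the reference
#: tunnel-ventilated house (velocities at zone centres and incoming
#: airflow through inlets/cooling pads, under 5- and 14-fan operation).
FIXTURES = (
    "velocity_5fans.csv",
    "velocity_14fans.csv",
    "airflow_inlets.csv",
    "airflow_totals.csv",
    "cooling_pad_profile.csv",
)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"comparison table is missing columns {missing}")
    if len(df) == 0:
        raise ValueError("comparison table is empty")
    return df


def load_comparison_table(path: str | Path) -> pd.DataFrame:
    """Read a location/measured/simulated/units CSV."""
    return _validate(pd.read_csv(path))


def list_fixtures() -> tuple[str, ...]:
    return FIXTURES


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged validation tables by file name."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("broilervent.data").joinpath(name)
    with resources.as_file(ref) as p:
        return _validate(pd.read_csv(p))


def signed_errors(table: pd.DataFrame) -> tuple[pd.Series, tuple[float, float]]:
    """Per-location signed error (measured - simulated) and its extremes.

    All rows must share one unit; a mixed-unit table is rejected.
    """
    _validate(table)
    units = set(table["units"])
    if len(units) != 1:
        raise ValueError(f"mixed units in comparison table: {sorted(units)}")
    err = (table["measured"] - table["simulated"]).astype(float)
    err.index = table["location"]
    return err, (float(err.min()), float(err.max()))


def agreement_percent(measured_total: float, simulated_total: float) -> float:
    """Simulated total as a percentage of the measured total."""
    if measured_total <= 0:
        raise ValueError("measured_total must be > 0")
    return 100.0 * simulated_total / measured_total


def rmse(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length series."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    if len(x) == 0:
        raise ValueError("series must contain at least one value")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def gradient_metric(zone_temps: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Longitudinal thermal gradient: mean(T3, T6) - mean(T1, T4).

    ``zone_temps`` must carry the six zone columns (``T1``..``T6`` or
    integer labels 1..6).  Positive values mean the near-fan zones are
    warmer than the far-end zones — the expected tunnel-ventilation
    gradient.  Returns the per-step series and summary statistics.
    """
    cols = {}
    for z in range(1, 7):
        if f"T{z}" in zone_temps.columns:
            cols[z] = f"T{z}"
        elif z in zone_temps.columns:
            cols[z] = z
        else:
            raise ValueError(f"zone {z} column missing from temperature table")
    near = (zone_temps[cols[3]].to_numpy() + zone_temps[cols[6]].to_numpy()) / 2.0
    far = (zone_temps[cols[1]].to_numpy() + zone_temps[cols[4]].to_numpy()) / 2.0
    series = pd.Series(near - far, index=zone_temps.index, name="near_minus_far")
    summary = {
        "mean": float(series.mean()),
        "min": float(series.min()),
        "max": float(series.max()),
        "final": float(series.iloc[-1]),
    }
    return series, summary
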