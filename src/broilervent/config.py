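"""Configuration files: build a full house setup from YAML/JSON.

A configuration file holds one mapping per component (``bird``,
``fan``, ``inlets``, ``cooling_pad``, ``circulation``, ``house``,
``simulation``); any omitted key falls back to the documented default,
and the fully resolved values — defaults included — are echoed into
the run manifest so every run records exactly what it used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .bird_thermal import BirdThermalParams, mixed_convection_resistance
from .ventilation_components import (
    CirculationFan,
    CoolingPad,
    FanCurve,
    InletRegistry,
)
from .zonal_simulator import HouseComponents, SimulationConfig, ZoneLayout

__all__ = ["HouseSetup", "load_setup"]

_SECTIONS = (
    "bird", "fan", "inlets", "cooling_pad", "circulation", "house", "simulation"
)

_HOUSE_DEFAULTS = {
    "length": 87.0, "width": 15.0, "eave": 3.5, "ridge": 5.0, "bird_height": 0.45,
}
_INLET_DEFAULTS = {"n_per_side": 29, "area": 0.3, "cd": 0.61, "fraction": 1.0}
_RA_DEFAULTS = {"h_natural": 4.2, "a": 9.0, "b": 0.6}


@dataclass(frozen=True)
class HouseSetup:
    """Resolved configuration: everything :func:`simulate` needs."""

    config: SimulationConfig
    layout: ZoneLayout
    components: HouseComponents
    bird: BirdThermalParams
    raw: dict

    def manifest(self) -> dict:
        """Run manifest: resolved parameter values, version and hash."""
        doc = json.dumps(self.raw, sort_keys=True)
        return {
            "package": "broilervent",
            "version": __version__,
            "config": self.raw,
            "config_sha256": hashlib.sha256(doc.encode()).hexdigest(),
        }


def _merged(section: Mapping | None, defaults: Mapping[str, Any]) -> dict:
    out = dict(defaults)
    if section:
        unknown = set(section) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out.update(section)
    return out


def _dataclass_defaults(cls) -> dict:
    out = {}
    for f in dataclasses.fields(cls):
        if f.default is not dataclasses.MISSING:
            out[f.name] = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            out[f.name] = f.default_factory()  # type: ignore[misc]
    return out


def load_setup(path: str | Path | None = None) -> HouseSetup:
    """Build the house setup from a YAML/JSON file (or pure defaults)."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(doc) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")

    bird_cfg = _merged(doc.get("bird"), _dataclass_defaults(BirdThermalParams))
    ra = bird_cfg.get("ra")
    if isinstance(ra, Mapping):
        bird_cfg["ra"] = mixed_convection_resistance(**_merged(ra, _RA_DEFAULTS))
        ra_echo: Any = dict(_merged(ra, _RA_DEFAULTS))
    elif callable(ra):
        ra_echo = dict(_RA_DEFAULTS)
    else:
        ra_echo = float(ra)
    bird = BirdThermalParams(**bird_cfg)

    fan = FanCurve(**_merged(doc.get("fan"), _dataclass_defaults(FanCurve)))
    inlets_cfg = _merged(doc.get("inlets"), _INLET_DEFAULTS)
    inlets = InletRegistry.default(**inlets_cfg)
    pad = CoolingPad(**_merged(doc.get("cooling_pad"), _dataclass_defaults(CoolingPad)))
    circ = CirculationFan(
        **_merged(doc.get("circulation"), _dataclass_defaults(CirculationFan))
    )
    house_cfg = _merged(doc.get("house"), _HOUSE_DEFAULTS)
    layout = ZoneLayout.default(**house_cfg)
    sim = SimulationConfig(
        **_merged(doc.get("simulation"), _dataclass_defaults(SimulationConfig))
    )

    raw = {
        "bird": {**{k: v for k, v in bird_cfg.items() if k != "ra"}, "ra": ra_echo},
        "fan": dataclasses.asdict(fan),
        "inlets": inlets_cfg,
        "cooling_pad": dataclasses.asdict(pad),
        "circulation": dataclasses.asdict(circ),
        "house": house_cfg,
        "simulation": {
            k: (v if not hasattr(v, "tolist") else v.tolist())
            for k, v in dataclasses.asdict(sim).items()
        },
    }
    return HouseSetup(
        config=sim,
        layout=layout,
        components=HouseComponents(
            fan_curve=fan, inlets=inlets, pad=pad, circulation=circ
        ),
        bird=bird,
        raw=raw,
    )
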