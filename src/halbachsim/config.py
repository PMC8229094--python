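"""Run configuration: YAML/JSON loading, unit parsing, validation.

Physical quantities in config files carry explicit unit suffixes
("1.0 mm", "22 mT", "10 fAm2", "1 mL/min") and are converted to SI on
load.  Bare numbers are taken as SI.  Validation collects every violation
before raising, so a bad file reports all its problems at once.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .flow import Channel, IBIDI_HEIGHTS
from .magnetics import MagnetArray
from .optimize import build_array
from .particle import FEMTO, CellModel, Fluid, MagnetizationModel
from .trajectory import SimulationConfig

__all__ = ["RunConfig", "ArraySpec", "load_config", "ConfigError", "GRADE_REMANENCE"]

#: default remanence by magnet grade (T); typical datasheet mid-values
GRADE_REMANENCE = {"N52": 1.45, "N45": 1.35}

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "t": 1.0, "mt": 1e-3,
    "am2": 1.0, "fam2": FEMTO,
    "pa.s": 1.0, "pa*s": 1.0, "mpa.s": 1e-3, "mpa*s": 1e-3,
    "kg/m3": 1.0, "g/cm3": 1e3,
    "m3/s": 1.0, "ml/min": 1e-6 / 60.0, "ul/min": 1e-9 / 60.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ][a-zA-Z0-9/.*µ]*)?\s*$")


class ConfigError(ValueError):
    """Raised with the full list of config violations."""


def parse_quantity(value: Any, name: str = "value") -> float:
    """'1.0 mm' -> 1e-3; bare numbers pass through as SI."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY_RE.match(str(value))
    if not m:
        raise ConfigError(f"{name}: cannot parse quantity {value!r}")
    num, unit = m.groups()
    if unit is None:
        return float(num)
    factor = _UNIT_FACTORS.get(unit.lower())
    if factor is None:
        raise ConfigError(f"{name}: unknown unit {unit!r} in {value!r}")
    return float(num) * factor


@dataclass(frozen=True)
class ArraySpec:
    """Declarative magnet-array description, buildable against a channel."""

    pattern: str = "halbach"
    element_width: float = 1.0e-3
    heights: tuple[float, float] = (2.75e-3, 2.0e-3)  # (vertical, horizontal)
    Br: float = GRADE_REMANENCE["N52"]
    span_margin: float = 10e-3
    phase: Optional[int] = None
    label: str = "array"

    def build(self, channel: Channel) -> MagnetArray:
        return build_array(
            self.pattern, self.element_width, self.heights, self.Br,
            channel, margin=self.span_margin, phase=self.phase,
        )


@dataclass(frozen=True)
class RunConfig:
    channel: Channel = Channel()
    fluid: Fluid = Fluid()
    cell: CellModel = CellModel()
    arrays: tuple[ArraySpec, ...] = (ArraySpec(),)
    simulation: SimulationConfig = SimulationConfig()
    raw: dict = field(default_factory=dict, compare=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SCHEMA = {
    "channel": {"preset", "height", "width", "length", "wall", "flow_rate"},
    "fluid": {"viscosity", "density"},
    "cell": {"radius", "density", "moment", "magnetization", "Bs"},
    "arrays": None,  # list handled separately
    "array": None,
    "simulation": {"n_cells", "rtol", "atol", "max_transit_factor", "capture_standoff"},
}
_ARRAY_KEYS = {"pattern", "element_width", "heights", "height", "grade", "Br",
               "span_margin", "phase", "label"}


def _build_channel(sec: dict, errors: list) -> Channel:
    kwargs = {}
    if "preset" in sec:
        preset = str(sec["preset"])
        if preset not in IBIDI_HEIGHTS:
            errors.append(f"channel.preset: unknown preset {preset!r}")
        else:
            kwargs["height"] = IBIDI_HEIGHTS[preset]
    for key in ("height", "width", "length", "wall", "flow_rate"):
        if key in sec:
            kwargs[key] = parse_quantity(sec[key], f"channel.{key}")
    try:
        return Channel(**kwargs)
    except ValueError as e:
        errors.append(f"channel: {e}")
        return Channel()


def _build_array_spec(sec: dict, idx: int, errors: list) -> ArraySpec:
    unknown = set(sec) - _ARRAY_KEYS
    if unknown:
        errors.append(f"arrays[{idx}]: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {"label": sec.get("label", f"array{idx}")}
    if "pattern" in sec:
        if sec["pattern"] not in ("halbach", "alternating"):
            errors.append(f"arrays[{idx}].pattern: must be halbach|alternating")
        else:
            kwargs["pattern"] = sec["pattern"]
    if "element_width" in sec:
        kwargs["element_width"] = parse_quantity(sec["element_width"], "element_width")
    if "heights" in sec:
        hs = sec["heights"]
        if not isinstance(hs, (list, tuple)) or len(hs) != 2:
            errors.append(f"arrays[{idx}].heights: need [vertical, horizontal]")
        else:
            kwargs["heights"] = tuple(parse_quantity(h, "heights") for h in hs)
    elif "height" in sec:
        h = parse_quantity(sec["height"], "height")
        kwargs["heights"] = (h, h)
    if "Br" in sec:
        kwargs["Br"] = parse_quantity(sec["Br"], "Br")
    elif "grade" in sec:
        grade = str(sec["grade"]).upper()
        if grade not in GRADE_REMANENCE:
            errors.append(f"arrays[{idx}].grade: unknown grade {grade!r}")
        else:
            kwargs["Br"] = GRADE_REMANENCE[grade]
    if "span_margin" in sec:
        kwargs["span_margin"] = parse_quantity(sec["span_margin"], "span_margin")
    if "phase" in sec:
        kwargs["phase"] = int(sec["phase"])
    try:
        return ArraySpec(**kwargs)
    except (TypeError, ValueError) as e:
        errors.append(f"arrays[{idx}]: {e}")
        return ArraySpec()


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the full default run (800-um channel, optimized
    Halbach array, 10 fAm^2 arctan cell).  All violations are reported
    together in one ConfigError.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() not in (".json",) else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    unknown = set(data) - set(_SCHEMA)
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")

    channel = _build_channel(data.get("channel", {}) or {}, errors)
    fsec = data.get("fluid", {}) or {}
    for k in set(fsec) - _SCHEMA["fluid"]:
        errors.append(f"fluid: unknown key {k!r}")
    try:
        fluid = Fluid(
            viscosity=parse_quantity(fsec.get("viscosity", 8.9e-4), "fluid.viscosity"),
            density=parse_quantity(fsec.get("density", 1000.0), "fluid.density"),
        )
    except ValueError as e:
        errors.append(f"fluid: {e}")
        fluid = Fluid()

    csec = data.get("cell", {}) or {}
    for k in set(csec) - _SCHEMA["cell"]:
        errors.append(f"cell: unknown key {k!r}")
    try:
        cell = CellModel(
            radius=parse_quantity(csec.get("radius", 5e-6), "cell.radius"),
            density=parse_quantity(csec.get("density", 1077.0), "cell.density"),
            magnetization=MagnetizationModel(
                variant=csec.get("magnetization", "arctan"),
                m_s=parse_quantity(csec.get("moment", "10 fAm2"), "cell.moment"),
                Bs=parse_quantity(csec.get("Bs", "22 mT"), "cell.Bs"),
            ),
        )
    except ValueError as e:
        errors.append(f"cell: {e}")
        cell = CellModel()

    arr_list = data.get("arrays")
    if arr_list is None and "array" in data:
        arr_list = [data["array"]]
    if arr_list is None:
        arrays = (ArraySpec(),)
    elif not isinstance(arr_list, list):
        errors.append("arrays: must be a list of array specs")
        arrays = (ArraySpec(),)
    else:
        arrays = tuple(_build_array_spec(a or {}, i, errors) for i, a in enumerate(arr_list))

    ssec = data.get("simulation", {}) or {}
    for k in set(ssec) - _SCHEMA["simulation"]:
        errors.append(f"simulation: unknown key {k!r}")
    try:
        sim = SimulationConfig(
            n_cells=int(ssec.get("n_cells", 500)),
            rtol=float(ssec.get("rtol", 1e-6)),
            atol=float(ssec.get("atol", 1e-9)),
            max_transit_factor=float(ssec.get("max_transit_factor", 20.0)),
            capture_standoff=(
                parse_quantity(ssec["capture_standoff"], "capture_standoff")
                if "capture_standoff" in ssec else None
            ),
        )
    except (TypeError, ValueError) as e:
        errors.append(f"simulation: {e}")
        sim = SimulationConfig()

    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(
        channel=channel, fluid=fluid, cell=cell, arrays=arrays,
        simulation=sim, raw=data,
    )


def dump_config(cfg: RunConfig) -> dict:
    """Round-trippable plain-dict form of a RunConfig (SI units)."""
    return {
        "channel": {
            "height": cfg.channel.height, "width": cfg.channel.width,
            "length": cfg.channel.length, "wall": cfg.channel.wall,
            "flow_rate": cfg.channel.flow_rate,
        },
        "fluid": {"viscosity": cfg.fluid.viscosity, "density": cfg.fluid.density},
        "cell": {
            "radius": cfg.cell.radius, "density": cfg.cell.density,
            "magnetization": cfg.cell.magnetization.variant,
            "moment": cfg.cell.magnetization.m_s, "Bs": cfg.cell.magnetization.Bs,
        },
        "arrays": [
            {
                "pattern": a.pattern, "element_width": a.element_width,
                "heights": list(a.heights), "Br": a.Br,
                "span_margin": a.span_margin,
                **({"phase": a.phase} if a.phase is not None else {}),
                "label": a.label,
            }
            for a in cfg.arrays
        ],
        "simulation": {
            "n_cells": cfg.simulation.n_cells, "rtol": cfg.simulation.rtol,
            "atol": cfg.simulation.atol,
            "max_transit_factor": cfg.simulation.max_transit_factor,
            **(
                {"capture_standoff": cfg.simulation.capture_standoff}
                if cfg.simulation.capture_standoff is not None else {}
            ),
        },
    }
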