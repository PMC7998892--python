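"""Run configuration: schema-validated YAML/JSON for designs, materials,
band windows, grids and schedules.

Unknown keys are rejected outright so a typo cannot silently fall back to
a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .bands import BandDefinition
from .errors import ConfigError
from .materials import (
    LorentzOscillatorParams,
    Material,
    MaterialSet,
    default_materials,
)
from .structure import AnodizationProfile, GifDesign

__all__ = [
    "RunConfig",
    "load_config",
    "design_from_dict",
    "material_from_dict",
    "config_hash",
]


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown keys in {context}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _dataclass_from_dict(cls, d: dict, context: str):
    names = [f.name for f in fields(cls)]
    _check_keys(d, names, context)
    try:
        return cls(**d)
    except TypeError as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def design_from_dict(d: dict) -> GifDesign:
    return _dataclass_from_dict(GifDesign, d, "design")


def anodization_from_dict(d: dict) -> AnodizationProfile:
    return _dataclass_from_dict(AnodizationProfile, d, "anodization")


def material_from_dict(d: dict) -> Material:
    """Build a material from {type: constant|cauchy|lorentz|table, ...}."""
    if "type" not in d:
        raise ConfigError("material definition needs a 'type' key")
    kind = d["type"]
    rest = {k: v for k, v in d.items() if k != "type"}
    if kind == "constant":
        _check_keys(rest, {"n", "k", "label"}, "constant material")
        return Material.constant(rest.get("n", 1.0), rest.get("k", 0.0),
                                 rest.get("label", "constant"))
    if kind == "cauchy":
        _check_keys(rest, {"a", "b", "label"}, "cauchy material")
        return Material.cauchy(rest["a"], rest.get("b", 0.0),
                               rest.get("label", "cauchy"))
    if kind == "lorentz":
        _check_keys(rest, {"eps_inf", "resonance_wavelength", "strength",
                           "damping", "label"}, "lorentz material")
        label = rest.pop("label", "lorentz")
        return Material.lorentz(LorentzOscillatorParams(**rest), label)
    if kind == "table":
        _check_keys(rest, {"path", "label"}, "table material")
        data = np.loadtxt(rest["path"], delimiter=",", skiprows=1, ndmin=2)
        k = data[:, 2] if data.shape[1] > 2 else None
        return Material.from_table(data[:, 0], data[:, 1], k,
                                   rest.get("label", "table"))
    raise ConfigError(f"unknown material type {kind!r}")


_TOP_KEYS = {"design", "anodization", "materials", "bands", "grid", "angle",
             "polarization", "seed", "schedule", "smooth_width"}


@dataclass
class RunConfig:
    """Validated configuration for a simulation or analysis run."""

    design: GifDesign = field(default_factory=GifDesign)
    anodization: AnodizationProfile | None = None
    materials: MaterialSet = field(default_factory=default_materials)
    bands: BandDefinition = field(default_factory=BandDefinition)
    wavelengths: np.ndarray | None = None
    angle: float = 0.0
    polarization: str = "unpolarized"
    seed: int = 0
    schedule: list = field(default_factory=list)
    smooth_width: int = 1
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cfg = RunConfig(raw=raw)
    if "design" in raw:
        cfg.design = design_from_dict(raw["design"])
    if "anodization" in raw:
        cfg.anodization = anodization_from_dict(raw["anodization"])
    if "materials" in raw:
        mats = raw["materials"]
        _check_keys(mats, {"host", "drug", "medium"}, "materials")
        base = default_materials()
        host = material_from_dict(mats["host"]) if "host" in mats else base.host
        drug = material_from_dict(mats["drug"]) if "drug" in mats else base.drug
        medium = material_from_dict(mats["medium"]) if "medium" in mats else None
        cfg.materials = MaterialSet(host=host, drug=drug, medium=medium)
    if "bands" in raw:
        b = raw["bands"]
        _check_keys(b, {"signal_window", "reference_window"}, "bands")
        cfg.bands = BandDefinition(
            signal_window=tuple(b.get("signal_window", (430.0, 560.0))),
            reference_window=tuple(b.get("reference_window", (600.0, 800.0))),
        )
    if "grid" in raw:
        g = raw["grid"]
        _check_keys(g, {"min", "max", "step"}, "grid")
        try:
            lo, hi = float(g["min"]), float(g["max"])
            step = float(g.get("step", 1.0))
        except KeyError as exc:
            raise ConfigError(f"grid needs 'min' and 'max': missing {exc}") from exc
        if not (lo < hi and step > 0):
            raise ConfigError("grid must satisfy min < max and step > 0")
        n = int(round((hi - lo) / step))
        cfg.wavelengths = lo + step * np.arange(n + 1)
    if "angle" in raw:
        cfg.angle = float(raw["angle"])
    if "polarization" in raw:
        cfg.polarization = str(raw["polarization"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "schedule" in raw:
        sched = raw["schedule"]
        if not isinstance(sched, list):
            raise ConfigError("schedule must be a list of [start_time_s, pH]")
        cfg.schedule = [(float(t), None if ph is None else float(ph))
                        for t, ph in sched]
    if "smooth_width" in raw:
        cfg.smooth_width = int(raw["smooth_width"])
    return cfg


def config_hash(raw: dict) -> str:
    """Stable short hash of a configuration mapping, for run logging."""
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
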