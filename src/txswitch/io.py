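"""Configuration loading, run manifests and deterministic result writers."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (CellContext, CooperativeSwitchSpec, IndirectSwitchSpec,
                     MultiTargetSpec, NflSpec, resolve_constant)
from .presets import PRESETS

__all__ = ["load_config", "spec_from_config", "RunManifest", "write_results"]

LN2 = math.log(2.0)

_COMMON = {"model", "omega_aL", "kf_aL_per_ymol_min", "halflife_min",
           "alpha_over_beta"}
_KEYS = {
    "cooperative": _COMMON | {"cooperativity_c", "Kr_ymol_per_aL", "RT_count",
                              "mode"},
    "indirect": _COMMON | {"mechanisms", "AT_count", "RT_count",
                           "constant_convention", "Ks_printed", "Ka_printed",
                           "Kb_printed", "Kd_printed"},
    "nfl": _COMMON | {"mechanisms", "AT_count", "alpha2_per_min",
                      "alpha3_per_min", "constant_convention", "Ks_printed",
                      "Ka_printed", "Kb_printed", "Kd_printed",
                      "table_literal"},
    "multitarget": _COMMON | {"mechanisms", "AT_count", "RT_count", "DT_count",
                              "constant_convention", "Ks_printed",
                              "Ka_printed", "Kb_printed", "Kd_printed"},
}
_REQUIRED = {
    "cooperative": {"cooperativity_c", "Kr_ymol_per_aL", "RT_count"},
    "indirect": {"mechanisms", "AT_count", "Ks_printed", "Ka_printed"},
    "nfl": {"mechanisms", "AT_count", "Ks_printed", "Ka_printed"},
    "multitarget": {"mechanisms", "AT_count", "Ks_printed", "Ka_printed"},
}


def load_config(path: str | Path) -> dict:
    """Read and validate a flat YAML config; returns the resolved mapping.

    Unknown keys, missing required keys and non-positive unit-bearing
    values raise errors naming the offending key."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return validate_config(raw, source=str(path))


def validate_config(cfg: dict, source: str = "<config>") -> dict:
    model = cfg.get("model")
    if model not in _KEYS:
        raise ValueError(f"{source}: key 'model' must be one of "
                         f"{sorted(_KEYS)}, got {model!r}")
    unknown = set(cfg) - _KEYS[model]
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)} "
                         f"for model {model!r}")
    missing = _REQUIRED[model] - set(cfg)
    if missing:
        raise ValueError(f"{source}: missing required keys {sorted(missing)}")
    for key in ("omega_aL", "kf_aL_per_ymol_min", "halflife_min",
                "alpha_over_beta"):
        if key in cfg and not cfg[key] > 0:
            raise ValueError(f"{source}: key {key!r} must be positive")
    out = dict(cfg)
    out.setdefault("omega_aL", 1e7)
    out.setdefault("kf_aL_per_ymol_min", 600.0)
    out.setdefault("halflife_min", 984.5)
    out.setdefault("alpha_over_beta", 100.0)
    if "constant_convention" in _KEYS[model]:
        out.setdefault("constant_convention", "per_activator")
    return out


def preset_config(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return validate_config(dict(PRESETS[name]), source=f"preset:{name}")


def _context(cfg: dict) -> CellContext:
    beta = LN2 / cfg["halflife_min"]
    return CellContext(omega=cfg["omega_aL"], kf=cfg["kf_aL_per_ymol_min"],
                       alpha=cfg["alpha_over_beta"] * beta, beta=beta)


def spec_from_config(cfg: dict):
    """Instantiate the model spec described by a validated config mapping."""
    ctx = _context(cfg)
    model = cfg["model"]
    if model == "cooperative":
        return CooperativeSwitchSpec(
            context=ctx, c=cfg["cooperativity_c"], Kr=cfg["Kr_ymol_per_aL"],
            RT=cfg.get("RT_count", 0.0),
            mode=cfg.get("mode", "repressor_inhibits"))
    conv = cfg["constant_convention"]
    at = cfg["AT_count"]
    res = lambda key: (None if cfg.get(key) is None else
                       resolve_constant(cfg[key], conv, at, ctx.omega))
    if model == "indirect":
        return IndirectSwitchSpec(
            context=ctx, AT=at, RT=cfg.get("RT_count", 0.0),
            Ks=res("Ks_printed"), Ka=res("Ka_printed"),
            Kb=res("Kb_printed") or 1.0, Kd=res("Kd_printed"),
            mechanisms=cfg["mechanisms"])
    if model == "nfl":
        return NflSpec(
            context=ctx, alpha2=cfg.get("alpha2_per_min", 5 / 12),
            alpha3=cfg.get("alpha3_per_min", 5 / 12), AT=at,
            Ks=res("Ks_printed"), Ka=res("Ka_printed"),
            Kb=res("Kb_printed") or 1.0, Kd=res("Kd_printed"),
            mechanisms=cfg["mechanisms"],
            table_literal=bool(cfg.get("table_literal", False)))
    return MultiTargetSpec(
        context=ctx, AT=at, RT=cfg.get("RT_count", 0.0),
        DT=int(cfg.get("DT_count", 0)), Ks=res("Ks_printed"),
        Ka=res("Ka_printed"), Kb=res("Kb_printed") or 1.0,
        Kd=res("Kd_printed"), mechanisms=cfg["mechanisms"])


@dataclass
class RunManifest:
    """Record of one CLI run: resolved parameters, seed, outputs."""

    command: str
    config: dict
    master_seed: int
    outdir: str
    files: list = field(default_factory=list)

    def register(self, path: Path) -> Path:
        self.files.append(str(path))
        return path

    def write(self) -> Path:
        path = Path(self.outdir) / "manifest.json"
        payload = {"command": self.command, "config": self.config,
                   "master_seed": self.master_seed,
                   "files": sorted(self.files)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
        return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(manifest: RunManifest, name: str, obj) -> Path:
    """Write a result deterministically (CSV for frames, JSON otherwise).

    Identical inputs produce byte-identical files: fixed float formatting,
    sorted JSON keys, no timestamps."""
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        path = outdir / f"{name}.csv"
        obj.to_csv(path, index=False, float_format="%.10g",
                   lineterminator="\n")
    else:
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
    return manifest.register(path)
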