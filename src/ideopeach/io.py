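"""Configuration loading, dataset round-tripping, and run manifests."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, fields
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .fruit_model import GrowthConfig, WeatherSeries
from .moea import NsgaConfig
from .progeny import ProgenySpec
from .study import Dataset

__all__ = ["Config", "load_config", "write_dataset", "read_dataset", "write_manifest"]

# repr-precision float formatting guarantees lossless CSV round-trips
_FLOAT_FMT = "%.17g"


@dataclass
class Config:
    """Validated bundle of the run-time configuration sections."""

    growth: GrowthConfig
    nsga: NsgaConfig
    progeny: ProgenySpec
    weather: WeatherSeries


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
                         f"expected a subset of {sorted(known)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {name!r}: {exc}") from exc


def _build_weather(section: dict) -> WeatherSeries:
    section = dict(section)
    kind = section.pop("kind", "constant")
    if kind == "constant":
        allowed = {"tmean", "base_temp", "start", "end"}
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in config section 'weather'")
        return WeatherSeries.constant(**section)
    if kind == "csv":
        path = section.pop("path", None)
        if path is None:
            raise ValueError("weather kind 'csv' needs a 'path' key")
        return WeatherSeries.read_csv(path, base_temp=section.pop("base_temp", 7.0))
    raise ValueError(f"unknown weather kind {kind!r}")


def load_config(path=None) -> Config:
    """Load and validate a YAML config; missing sections get full defaults.

    Unknown keys and out-of-range values are rejected with messages naming
    the offending section and field.
    """
    payload = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError("config file must contain a mapping")
    unknown = set(payload) - {"growth", "nsga", "progeny", "weather"}
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}")
    ve = payload.get("progeny", {})
    return Config(
        growth=_build(GrowthConfig, payload.get("growth", {}), "growth"),
        nsga=_build(NsgaConfig, payload.get("nsga", {}), "nsga"),
        progeny=_build(ProgenySpec, _tupled(ve), "progeny"),
        weather=_build_weather(payload.get("weather", {})),
    )


def _tupled(section: dict) -> dict:
    section = dict(section)
    if "fruit_size_factors" in section:
        section["fruit_size_factors"] = tuple(section["fruit_size_factors"])
    return section


def write_dataset(ds: Dataset, path) -> None:
    """One tidy CSV per dataset; floats at repr precision for lossless reads."""
    frame = ds.to_frame()
    frame.insert(1, "provenance", ds.provenance)
    frame.insert(2, "seed", ds.seed)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dataset(path) -> Dataset:
    frame = pd.read_csv(path, float_precision="round_trip")
    name = str(frame["dataset"].iloc[0])
    provenance = str(frame["provenance"].iloc[0])
    seed = int(frame["seed"].iloc[0])
    param_cols = [c for c in frame.columns if c.startswith("param_")]
    pheno_cols = ["DM", "SR", "SU"]
    meta = {"dataset", "provenance", "seed", *param_cols, *pheno_cols}
    dec_cols = [c for c in frame.columns if c not in meta]
    return Dataset(
        name=name,
        decisions=frame[dec_cols].copy(),
        parameters=frame[param_cols].rename(columns=lambda c: c[len("param_"):]).copy(),
        phenotypes=frame[pheno_cols].copy(),
        provenance=provenance,
        seed=seed,
    )


def write_manifest(path, command: str, seed, config_snapshot: dict, outputs: dict) -> None:
    """Atomically write a replayable run manifest (JSON) next to the results."""
    from . import __version__

    checksums = {}
    for label, out_path in outputs.items():
        with open(out_path, "rb") as fh:
            checksums[label] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "command": command,
        "seed": seed,
        "config": config_snapshot,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "output_checksums": checksums,
    }
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".manifest")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(manifest, fh, indent=1, default=_jsonable)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def config_snapshot(cfg: Config) -> dict:
    from dataclasses import asdict

    return {
        "growth": asdict(cfg.growth),
        "nsga": asdict(cfg.nsga),
        "progeny": {**asdict(cfg.progeny)},
        "weather": {"base_temp": cfg.weather.base_temp,
                    "days": [float(cfg.weather.days[0]), float(cfg.weather.days[-1])],
                    "tmean_mean": float(np.mean(cfg.weather.tmean))},
    }
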