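"""Configuration parsing, tabular output and run manifests."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .parameters import DAYS_PER_WEEK, EmpiricalObservables, human_observables

_OBS_KEYS = {"N", "n_star", "s_star", "beta_per_day", "beta_per_week",
             "ell_minutes", "epsilon", "alpha", "rho", "human_preset"}

#: Documented defaults: murine observables with the small blood pool /
#: fast transit end of the reported ranges.
_DEFAULTS = dict(N=10_000, n_star=9_900.0, s_star=100.0,
                 beta_per_day=1.0 / 39.0, ell_minutes=1.0,
                 epsilon=0.0, alpha=0.0, rho=0.0)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunOptions:
    epsilon: float = 0.0
    alpha: float = 0.0
    rho: float = 0.0
    extra: dict = field(default_factory=dict)


def parse_config(path: str | Path) -> tuple[EmpiricalObservables, RunOptions]:
    """Read a flat YAML or JSON key-value config into observables + options.

    Recognised keys: ``N, n_star, s_star, beta_per_day`` (or
    ``beta_per_week``), ``ell_minutes, epsilon, alpha, rho`` and the
    boolean ``human_preset`` (human-scale defaults for the given N).
    Missing keys fall back to the murine defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config must be a flat mapping, got {type(raw).__name__}")
    unknown = set(raw) - _OBS_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "beta_per_day" in raw and "beta_per_week" in raw:
        raise ConfigError("give beta_per_day or beta_per_week, not both")
    cfg = dict(_DEFAULTS)
    cfg.update({k: raw[k] for k in raw if k not in ("human_preset", "beta_per_week")})
    if "beta_per_week" in raw:
        cfg["beta_per_day"] = float(raw["beta_per_week"]) / DAYS_PER_WEEK
    for key in ("n_star", "s_star", "beta_per_day", "ell_minutes"):
        if float(cfg[key]) <= 0:
            raise ConfigError(f"config key '{key}' must be positive, got {cfg[key]}")
    if raw.get("human_preset"):
        obs = human_observables(int(cfg["N"]))
    else:
        try:
            obs = EmpiricalObservables(N=int(cfg["N"]), n_star=float(cfg["n_star"]),
                                       s_star=float(cfg["s_star"]),
                                       beta=float(cfg["beta_per_day"]),
                                       ell_minutes=float(cfg["ell_minutes"]))
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    opts = RunOptions(epsilon=float(cfg["epsilon"]), alpha=float(cfg["alpha"]),
                      rho=float(cfg["rho"]))
    return obs, opts


def write_table(records, path: str | Path, manifest: Mapping[str, Any] | None = None) -> Path:
    """Write records (DataFrame or list of dicts) as TSV with a header row,
    deterministic column order and round-trippable float precision.

    When ``manifest`` is given, a JSON manifest is written alongside
    (``<path>.manifest.json``).
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        write_manifest(path.with_suffix(path.suffix + ".manifest.json"),
                       outputs=[str(path)], **manifest)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, command: str = "", seed: int | None = None,
                   parameters: Mapping[str, Any] | None = None,
                   outputs: list[str] | None = None) -> Path:
    """Reproducibility metadata written alongside every output table."""
    path = Path(path)
    doc = {
        "tool": "hscniche",
        "version": __version__,
        "command": command,
        "seed": seed,
        "parameters": dict(parameters or {}),
        "outputs": outputs or [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return path
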