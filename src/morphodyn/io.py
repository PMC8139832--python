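"""CSV/JSON/YAML input-output for simulation snapshots, traces and reports.

All on-disk formats are plain text so any stage can be run standalone on
files produced by any other stage:

* snapshots    CSV with columns x, u, v (one file per recorded time);
* FDAP traces  CSV with columns frame, time_s, intensity;
* FCS curves   CSV with columns tau_s, G[, sd];
* raw traces   CSV with columns t_s, counts;
* fit reports  JSON;
* run configs  YAML or JSON (picked by file extension).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fcs import CorrelationCurve
from .fdap import FDAPTrace
from .reaction_diffusion import LigandState, SpatialGrid

__all__ = [
    "write_snapshot", "read_snapshot",
    "write_fdap_trace", "read_fdap_trace",
    "write_correlation_curve", "read_correlation_curve",
    "write_raw_trace", "read_raw_trace",
    "write_json_report", "load_config", "dump_config",
    "validate_config", "ConfigError",
]


class ConfigError(ValueError):
    """A run configuration failed schema validation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


# ---------------------------------------------------------------- snapshots

def write_snapshot(path, state: LigandState, grid: SpatialGrid) -> None:
    df = pd.DataFrame({"x": grid.x, "u": state.u, "v": state.v})
    df.to_csv(path, index=False)


def read_snapshot(path):
    """Returns (state, grid) rebuilt from a snapshot CSV."""
    df = pd.read_csv(path)
    x = df["x"].to_numpy()
    grid = SpatialGrid(L=float(x[-1]), dx=float(x[1] - x[0]))
    state = LigandState(u=df["u"].to_numpy(), v=df["v"].to_numpy())
    return state, grid


# ---------------------------------------------------------------- FDAP

def write_fdap_trace(path, trace: FDAPTrace) -> None:
    pd.DataFrame({"frame": trace.frame, "time_s": trace.t,
                  "intensity": trace.intensity}).to_csv(path, index=False)


def read_fdap_trace(path, meta: dict | None = None) -> FDAPTrace:
    df = pd.read_csv(path)
    return FDAPTrace(t=df["time_s"].to_numpy(), frame=df["frame"].to_numpy(),
                     intensity=df["intensity"].to_numpy(), meta=meta or {})


# ---------------------------------------------------------------- FCS

def write_correlation_curve(path, curve: CorrelationCurve) -> None:
    data = {"tau_s": curve.tau, "G": curve.G}
    if curve.weights is not None:
        data["sd"] = curve.weights
    pd.DataFrame(data).to_csv(path, index=False)


def read_correlation_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    weights = df["sd"].to_numpy() if "sd" in df.columns else None
    return CorrelationCurve(tau=df["tau_s"].to_numpy(), G=df["G"].to_numpy(),
                            weights=weights)


def write_raw_trace(path, counts, dt: float) -> None:
    t = np.arange(len(counts)) * dt
    pd.DataFrame({"t_s": t, "counts": np.asarray(counts)}).to_csv(path, index=False)


def read_raw_trace(path):
    """Returns (counts, dt) from a raw intensity-trace CSV."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return df["counts"].to_numpy(dtype=float), dt


# ---------------------------------------------------------------- reports & config

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(path, report) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


_SCENARIO_KINDS = {"periodic", "random_halfnormal", "band", "absent_beyond", "zero"}

_REQUIRED_KEYS = {"L", "dx", "dt", "t_end", "D", "b", "c", "g_max", "R", "scenario"}
_OPTIONAL_KEYS = {"record_every", "label_region", "pc_t_end"}


def validate_config(cfg: dict) -> list[str]:
    """Collect all schema violations (empty list means valid)."""
    errors = []
    if not isinstance(cfg, dict):
        return ["configuration must be a mapping"]
    missing = _REQUIRED_KEYS - cfg.keys()
    errors += [f"missing key: {k}" for k in sorted(missing)]
    unknown = cfg.keys() - _REQUIRED_KEYS - _OPTIONAL_KEYS
    errors += [f"unknown key: {k}" for k in sorted(unknown)]
    for key in ("L", "dx", "dt", "t_end", "g_max", "R"):
        if key in cfg and not (isinstance(cfg[key], (int, float)) and cfg[key] > 0):
            if key == "g_max" and isinstance(cfg.get(key), (int, float)) and cfg[key] == 0:
                continue
            errors.append(f"{key} must be a positive number")
    for key in ("D", "b", "c"):
        if key in cfg and not (isinstance(cfg[key], (int, float)) and cfg[key] >= 0):
            errors.append(f"{key} must be a non-negative number")
    if all(k in cfg for k in ("D", "dt", "dx")) and \
            isinstance(cfg["D"], (int, float)) and cfg.get("dx", 0) > 0 and cfg.get("dt", 0) > 0:
        s = cfg["D"] * cfg["dt"] / cfg["dx"] ** 2
        if s >= 0.5:
            errors.append(f"stability violated: D*dt/dx^2 = {s:.4g} >= 0.5")
    scen = cfg.get("scenario")
    if scen is not None:
        if not isinstance(scen, dict):
            errors.append("scenario must be a mapping")
        else:
            kind = scen.get("kind")
            if kind not in _SCENARIO_KINDS:
                errors.append(f"scenario.kind must be one of {sorted(_SCENARIO_KINDS)}")
            if kind == "random_halfnormal" and scen.get("seed") is None:
                errors.append("random_halfnormal scenario requires scenario.seed")
            if kind == "band" and scen.get("band") is None:
                errors.append("band scenario requires scenario.band = [lo, hi]")
    return errors


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)
    return cfg


def dump_config(path, cfg: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
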