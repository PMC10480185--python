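"""Configuration loading, result serialization and run manifests.

A single YAML file configures a run or sweep; omitted keys fall back to the
documented defaults (mu = 0.5, distance floor 1e-4, gap threshold 0.01,
occupancy band 0.01). Results are written as a CSV table plus a JSON manifest
sufficient to reproduce every run it indexes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .core import ModelConfig
from .experiments import GridSpec
from .runner import StoppingRule

__all__ = ["RunSettings", "load_config", "write_results", "read_results", "make_manifest"]

_MODEL_KEYS = {
    "epsilon",
    "gamma",
    "mu",
    "p_m",
    "distance_floor",
    "max_iterations",
    "seed",
}
_GRID_KEYS = {"p_m_values", "epsilon_values", "gamma_values", "n_runs", "n_agents"}
_STOP_KEYS = {"kind", "check_stride", "patience", "change_threshold", "gap_threshold"}
_TOP_KEYS = {"n_agents", "scenario", "grid", "stopping"} | _MODEL_KEYS


@dataclass
class RunSettings:
    """Validated bundle: model parameters, grid, stopping rule and metadata."""

    model: ModelConfig
    grid: GridSpec
    stop: StoppingRule
    n_agents: int
    scenario: str | None = None


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {where} key(s): {sorted(unknown)}")


def load_config(path) -> RunSettings:
    """Parse and validate a YAML configuration file.

    ``n_agents`` is required; ``epsilon`` given as a list enables heterogeneous
    mode (its length must equal ``n_agents``). Unknown or out-of-range keys
    raise errors naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "configuration")
    if "n_agents" not in raw:
        raise ValueError("configuration must set n_agents")
    n_agents = int(raw["n_agents"])

    model_kwargs = {k: raw[k] for k in _MODEL_KEYS if k in raw}
    model_kwargs.setdefault("epsilon", 0.5)
    model = ModelConfig(**model_kwargs)
    if model.heterogeneous and len(model.epsilon) != n_agents:
        raise ValueError(
            f"epsilon list has length {len(model.epsilon)} but n_agents={n_agents}"
        )

    grid_raw = dict(raw.get("grid") or {})
    _reject_unknown(grid_raw, _GRID_KEYS, "grid")
    for key in ("p_m_values", "epsilon_values", "gamma_values"):
        if key in grid_raw:
            grid_raw[key] = tuple(grid_raw[key])
    grid_raw.setdefault("n_agents", n_agents)
    grid = GridSpec(**grid_raw)

    stop_raw = dict(raw.get("stopping") or {})
    _reject_unknown(stop_raw, _STOP_KEYS, "stopping")
    stop = StoppingRule(**stop_raw) if stop_raw else StoppingRule.cluster_equilibrium()

    return RunSettings(
        model=model,
        grid=grid,
        stop=stop,
        n_agents=n_agents,
        scenario=raw.get("scenario"),
    )


def _package_version() -> str:
    try:
        return version("bcmedia")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def make_manifest(config: dict, seeds: list[int], outputs: list[str] | None = None) -> dict:
    """Manifest sufficient to bit-reproduce the runs it indexes."""
    return {
        "artifact_version": _package_version(),
        "created": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": list(map(int, seeds)),
        "outputs": outputs or [],
    }


def write_results(table: pd.DataFrame, manifest: dict, out_dir) -> dict[str, Path]:
    """Write the results CSV and its JSON manifest; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    manifest_path = out_dir / "manifest.json"
    table.to_csv(csv_path, index=False)
    manifest = dict(manifest)
    manifest["outputs"] = [csv_path.name]
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return {"results": csv_path, "manifest": manifest_path}


def read_results(out_dir) -> tuple[pd.DataFrame, dict]:
    """Inverse of :func:`write_results` (lossless round-trip of the table)."""
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / "results.csv")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return table, manifest
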