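"""YAML run-configuration loading and the run manifest.

A run configuration names the landscape geometry, the seed and the
scenario blocks (elasticities, allowed-conversion matrix, optional
demand CSV, iteration controls). Validation is strict: unknown keys are
rejected by name, defaults are filled in and echoed back on the loaded
object so a manifest records exactly what ran.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .rasterkit import CLASS_CODES, N_CLASSES

__all__ = ["RunConfig", "ScenarioBlock", "load_config", "RunManifest"]

_TOP_KEYS = {"seed", "nrows", "ncols", "cellsize", "scenarios"}
_SCENARIO_KEYS = {
    "elas",
    "allowed",
    "forbidden",
    "demand_csv",
    "max_iterations",
    "tolerance_ha",
    "damping",
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "nrows": 200,
    "ncols": 200,
    "cellsize": 60.0,
}


@dataclass
class ScenarioBlock:
    name: str
    elas: list[float]
    allowed: np.ndarray
    demand_csv: str | None = None
    max_iterations: int = 2000
    tolerance_ha: float | None = None
    damping: float = 0.5


@dataclass
class RunConfig:
    seed: int
    nrows: int
    ncols: int
    cellsize: float
    scenarios: dict[str, ScenarioBlock]
    source: dict = field(default_factory=dict)


def _type_error(key: str, expected: str, got) -> ValueError:
    return ValueError(f"config key {key!r}: expected {expected}, got {got!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **doc}
    for key, typ in (("seed", int), ("nrows", int), ("ncols", int)):
        if not isinstance(merged[key], int):
            raise _type_error(key, "integer", merged[key])
    if not isinstance(merged["cellsize"], (int, float)):
        raise _type_error("cellsize", "number", merged["cellsize"])

    raw_sc = merged.get("scenarios") or {}
    if not isinstance(raw_sc, dict) or not raw_sc:
        raise ValueError("config needs a non-empty 'scenarios' mapping")
    scenarios: dict[str, ScenarioBlock] = {}
    for name, block in raw_sc.items():
        if not isinstance(block, dict):
            raise _type_error(f"scenarios.{name}", "mapping", block)
        unknown = set(block) - _SCENARIO_KEYS
        if unknown:
            raise ValueError(f"scenarios.{name}: unknown keys {sorted(unknown)}")
        if "elas" not in block:
            raise ValueError(f"scenarios.{name}: missing required key 'elas'")
        elas = block["elas"]
        if not isinstance(elas, (list, tuple)) or len(elas) != N_CLASSES:
            raise _type_error(f"scenarios.{name}.elas", "list of 6 numbers", elas)
        elas = [float(v) for v in elas]
        if any(v < 0 or v > 1 for v in elas):
            raise ValueError(f"scenarios.{name}.elas: values must lie in [0, 1]")
        allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
        if "allowed" in block:
            a = np.asarray(block["allowed"], dtype=bool)
            if a.shape != (N_CLASSES, N_CLASSES):
                raise _type_error(f"scenarios.{name}.allowed", "6×6 matrix", block["allowed"])
            allowed = a
        for pair in block.get("forbidden", []) or []:
            if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                raise _type_error(
                    f"scenarios.{name}.forbidden", "list of [from, to] pairs", pair
                )
            src, dst = int(pair[0]), int(pair[1])
            if src not in CLASS_CODES or dst not in CLASS_CODES:
                raise ValueError(f"scenarios.{name}.forbidden: codes must be 1..6")
            if src != dst:
                allowed[src - 1, dst - 1] = False
        np.fill_diagonal(allowed, True)
        scenarios[name] = ScenarioBlock(
            name=name,
            elas=elas,
            allowed=allowed,
            demand_csv=block.get("demand_csv"),
            max_iterations=int(block.get("max_iterations", 2000)),
            tolerance_ha=(
                float(block["tolerance_ha"]) if block.get("tolerance_ha") is not None else None
            ),
            damping=float(block.get("damping", 0.5)),
        )
    return RunConfig(
        seed=int(merged["seed"]),
        nrows=int(merged["nrows"]),
        ncols=int(merged["ncols"]),
        cellsize=float(merged["cellsize"]),
        scenarios=scenarios,
        source=doc,
    )


@dataclass
class RunManifest:
    """Record of one pipeline run: config digest, seed, stage outputs."""

    seed: int
    config_digest: str
    tool_version: str
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    @classmethod
    def for_config(cls, config_doc: dict, seed: int, version: str) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config_doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return cls(seed=seed, config_digest=digest, tool_version=version)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = {k: str(v) if isinstance(v, Path) else v for k, v in info.items()}

    def save(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "tool_version": self.tool_version,
            "started": self.started,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(doc, indent=2))
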