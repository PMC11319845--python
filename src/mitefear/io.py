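"""Configuration files, CSV surfaces, and the run manifest.

Everything the pipeline reads or writes is plain text: YAML for
configuration and the run manifest, CSV for trajectories, summaries and
the per-scenario resolved vital rates.  The manifest written next to
each run's outputs snapshots the fully resolved configuration (plus the
calibration result actually used), and is itself accepted anywhere a
config file is, so a run can be reproduced bit-identically from its own
manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import math
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult
from .engine import ReplicateSet
from .lifecycle import VitalRates, default_baseline
from .params import (
    SCENARIO_IDS,
    EffectEstimate,
    EffectTable,
    ExperimentDesign,
    default_effect_table,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "trajectories_frame",
    "write_trajectories",
    "read_trajectories",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved experiment configuration."""

    design: ExperimentDesign
    baseline: VitalRates
    effects: EffectTable
    scenarios: tuple[str, ...] = SCENARIO_IDS
    calibration_tolerance: float = 0.01
    calibration_max_iter: int = 30
    calibration_replicates: int = 200

    def to_dict(self) -> dict[str, Any]:
        baseline = dataclasses.asdict(self.baseline)
        if math.isinf(baseline["recruitment_capacity"]):
            baseline["recruitment_capacity"] = ".inf"
        effects: dict[str, Any] = {}
        for f in dataclasses.fields(self.effects):
            v = getattr(self.effects, f.name)
            effects[f.name] = dataclasses.asdict(v) if isinstance(v, EffectEstimate) else v
        return {
            "design": dataclasses.asdict(self.design),
            "scenarios": list(self.scenarios),
            "baseline": baseline,
            "effects": effects,
            "calibration": {
                "tolerance": self.calibration_tolerance,
                "max_iter": self.calibration_max_iter,
                "replicates": self.calibration_replicates,
            },
        }


def _build(section: str, cls, defaults, overrides: dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(
            f"{section}: unknown field(s) {sorted(unknown)}; valid fields are "
            f"{sorted(valid)}"
        )
    try:
        return dataclasses.replace(defaults, **overrides)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML config (or build the default one).

    Every field is optional; omitted fields take the package defaults,
    which are the study conditions.  A run manifest (which nests the
    resolved config under ``config``) is accepted as well.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded.get("config", loaded)  # accept a manifest transparently
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    known = {"design", "scenarios", "baseline", "effects", "calibration"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level section(s) {sorted(unknown)}")

    design = _build("design", ExperimentDesign, ExperimentDesign(), raw.get("design", {}))

    baseline_raw = dict(raw.get("baseline", {}))
    # convenience aliases
    if "adult_mean_lifespan" in baseline_raw:
        lifespan = float(baseline_raw.pop("adult_mean_lifespan"))
        if lifespan <= 1:
            raise ConfigError("baseline: adult_mean_lifespan must exceed 1 day")
        s = 1.0 - 1.0 / lifespan
        baseline_raw.setdefault("adult_daily_survival_uninfected", s)
        baseline_raw.setdefault("adult_daily_survival_infected", s)
    if "daily_fecundity" in baseline_raw:
        fec = float(baseline_raw.pop("daily_fecundity"))
        baseline_raw.setdefault("daily_fecundity_uninfected", fec)
        baseline_raw.setdefault("daily_fecundity_infected", fec)
    if baseline_raw.get("recruitment_capacity") in (".inf", "inf", "Infinity"):
        baseline_raw["recruitment_capacity"] = math.inf
    baseline = _build("baseline", VitalRates, default_baseline(), baseline_raw)

    effects_raw = raw.get("effects", {})
    effects_defaults = default_effect_table()
    eff_overrides: dict[str, Any] = {}
    for name, value in effects_raw.items():
        if name == "target_prevalence":
            eff_overrides[name] = float(value)
            continue
        if not hasattr(effects_defaults, name):
            raise ConfigError(f"effects: unknown effect {name!r}")
        current: EffectEstimate = getattr(effects_defaults, name)
        if isinstance(value, dict):
            eff_overrides[name] = _build(f"effects.{name}", EffectEstimate, current, value)
        else:
            eff_overrides[name] = dataclasses.replace(current, point=float(value))
    effects = _build("effects", EffectTable, effects_defaults, eff_overrides)

    cal = raw.get("calibration", {})
    unknown = set(cal) - {"tolerance", "max_iter", "replicates"}
    if unknown:
        raise ConfigError(f"calibration: unknown field(s) {sorted(unknown)}")

    scenarios = raw.get("scenarios", list(SCENARIO_IDS))
    scenarios = tuple(str(s).upper() for s in scenarios)
    bad = [s for s in scenarios if s not in SCENARIO_IDS]
    if bad:
        raise ConfigError(
            f"scenarios: unknown id(s) {bad}; valid ids are {', '.join(SCENARIO_IDS)}"
        )

    return RunConfig(
        design=design,
        baseline=baseline,
        effects=effects,
        scenarios=scenarios,
        calibration_tolerance=float(cal.get("tolerance", 0.01)),
        calibration_max_iter=int(cal.get("max_iter", 30)),
        calibration_replicates=int(cal.get("replicates", 200)),
    )


def trajectories_frame(rep_sets: dict[str, ReplicateSet] | list[ReplicateSet]) -> pd.DataFrame:
    """Long-format trajectory table:
    scenario, replicate, day, adults_uninfected, adults_infected."""
    if isinstance(rep_sets, dict):
        rep_sets = [rep_sets[k] for k in sorted(rep_sets)]
    frames = []
    for rs in rep_sets:
        n, h1 = rs.uninfected_trajectories.shape
        frames.append(
            pd.DataFrame(
                {
                    "scenario": rs.scenario.id,
                    "replicate": np.repeat(np.arange(n), h1),
                    "day": np.tile(np.arange(h1), n),
                    "adults_uninfected": rs.uninfected_trajectories.ravel(),
                    "adults_infected": rs.infected_trajectories.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trajectories(rep_sets, path: str | Path) -> None:
    trajectories_frame(rep_sets).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"scenario", "replicate", "day", "adults_uninfected", "adults_infected"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    return df


@dataclass(frozen=True)
class RunManifest:
    config: RunConfig
    calibration: CalibrationResult | None
    package_version: str
    timestamp: str


def write_manifest(
    outdir: str | Path,
    config: RunConfig,
    calibration: CalibrationResult | None,
) -> Path:
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "master_seed": config.design.master_seed,
        "calibration": calibration.as_dict() if calibration is not None else None,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    path = Path(outdir) / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
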