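"""Pipeline configuration, orchestration and reproducibility manifests.

One YAML config file (all keys optional, unknown keys rejected) drives both
pipelines; a single master seed fans out to the named substreams
(simulation, imputation, down-sampling replicates) so one number reproduces
a run bit-identically. Every run writes a manifest recording the config
snapshot, seeds, stage-by-stage row counts and the package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .classify import ClassifyConfig, run_classification
from .interactome import (
    InteractomeConfig,
    differential_interactome,
    read_protein_groups,
)
from .mobility import MobilitySummary, calibrate_gates, assign_gate, summarize_mobility
from .msd import FeatureConfig
from .tracks_io import read_track_table

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigError",
    "parse_config",
    "run_smt_pipeline",
    "run_interactome_pipeline",
]

log = logging.getLogger("mobint")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class ConfigError(ValueError):
    """Config file malformed, unknown key, or out-of-range value."""


@dataclass(frozen=True)
class MobilityConfig:
    lo_pct: float = 75.0
    hi_pct: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.lo_pct < self.hi_pct < 100:
            raise ValueError("need 0 < lo_pct < hi_pct < 100")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated settings for both pipelines plus the master seed."""

    seed: int = 0
    frame_interval_s: float = 0.01
    coord_scale: float = 1.0
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    mobility: MobilityConfig = field(default_factory=MobilityConfig)
    interactome: InteractomeConfig = field(default_factory=InteractomeConfig)

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.coord_scale <= 0:
            raise ValueError("coord_scale must be > 0")


_SECTIONS: dict[str, type] = {
    "classify": ClassifyConfig,
    "features": FeatureConfig,
    "mobility": MobilityConfig,
    "interactome": InteractomeConfig,
}
_TOP_SCALARS = ("seed", "frame_interval_s", "coord_scale")


def _build_section(cls: type, data: Mapping[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] settings: {exc}") from exc


def parse_config(path: str | Path | None = None) -> PipelineConfig:
    """Parse a YAML config file; missing keys take their defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data = loaded
    unknown = set(data) - set(_SECTIONS) - set(_TOP_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {k: data[k] for k in _TOP_SCALARS if k in data}
    feat = _build_section(FeatureConfig, data.get("features", {}), "features")
    cls_data = dict(data.get("classify", {}))
    cls_data.setdefault("seed", kwargs.get("seed", 0))
    classify = _build_section(
        ClassifyConfig, {**cls_data, "features": feat}, "classify"
    )
    mobility = _build_section(MobilityConfig, data.get("mobility", {}), "mobility")
    int_data = dict(data.get("interactome", {}))
    int_data.setdefault("seed", kwargs.get("seed", 0))
    inter = _build_section(InteractomeConfig, int_data, "interactome")
    try:
        return PipelineConfig(
            classify=classify, mobility=mobility, interactome=inter, **kwargs
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _config_snapshot(config: PipelineConfig) -> dict:
    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (list, tuple)):
            return [as_dict(x) for x in obj]
        return obj

    return as_dict(config)


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    pipeline: str
    config: dict
    seeds: dict
    stage_counts: dict
    inputs: dict
    outputs: list
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def run_smt_pipeline(
    config: PipelineConfig,
    tracks_path: str | Path,
    out_dir: str | Path,
    h2b_path: str | Path | None = None,
) -> RunManifest:
    """Classify a track table end to end; gate against H2B when provided.

    Writes the classified feature table, per-replicate tables, an optional
    gate-labelled table and mobility summary, and a run manifest. Without an
    H2B calibration table the mobility stage is skipped with a warning.
    """
    tracks_path = Path(tracks_path)
    if not tracks_path.exists():
        raise FileNotFoundError(f"track table not found: {tracks_path}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ts = read_track_table(
        tracks_path,
        frame_interval_s=config.frame_interval_s,
        coord_scale=config.coord_scale,
    )
    log.info("read %d tracks from %s", len(ts), tracks_path)
    result = run_classification(ts, config.classify)
    for stage, count in result.stage_log.items():
        log.info("classify: %s = %d", stage, count)

    outputs = []
    feat_path = out_dir / "features.csv"
    result.features.to_csv(feat_path, index=False)
    outputs.append(str(feat_path))
    for i, rep in enumerate(result.replicates):
        p = out_dir / f"replicate_{i}.csv"
        rep.to_csv(p, index=False)
        outputs.append(str(p))

    summary_obj: dict[str, Any] = {"stage_log": result.stage_log}
    if h2b_path is not None and Path(h2b_path).exists():
        h2b_ts = read_track_table(
            h2b_path,
            frame_interval_s=config.frame_interval_s,
            coord_scale=config.coord_scale,
        )
        h2b_result = run_classification(h2b_ts, config.classify)
        gates = calibrate_gates(
            h2b_result.features, config.mobility.lo_pct, config.mobility.hi_pct
        )
        labelled = result.features.copy()
        labelled["mobility_gate"] = assign_gate(result.features, gates)
        lab_path = out_dir / "features_gated.csv"
        labelled.to_csv(lab_path, index=False)
        outputs.append(str(lab_path))
        summary = summarize_mobility(result.replicates, gates)
        summ_path = out_dir / "mobility_summary.csv"
        summary.per_replicate.to_csv(summ_path, index=False)
        outputs.append(str(summ_path))
        summary_obj["gates"] = {
            g.name: {
                "r_conf_min": g.r_conf_min,
                "r_conf_max": g.r_conf_max,
                "mean_jump_min": g.mean_jump_min,
                "mean_jump_max": g.mean_jump_max,
            }
            for g in gates
        }
        summary_obj["mobility"] = {
            gate: dict(summary.stats.loc[gate]) for gate in summary.stats.index
        }
    else:
        if h2b_path is not None:
            log.warning(
                "H2B calibration table %s not found; mobility stage skipped",
                h2b_path,
            )
        else:
            log.info("no H2B calibration table supplied; mobility stage skipped")

    summ_json = out_dir / "summary.json"
    summ_json.write_text(json.dumps(summary_obj, indent=2, default=float) + "\n")
    outputs.append(str(summ_json))

    manifest = RunManifest(
        pipeline="smt",
        config=_config_snapshot(config),
        seeds={
            "master": config.seed,
            "downsample_replicates": [
                config.classify.seed + i
                for i in range(config.classify.downsample_reps)
            ],
        },
        stage_counts=result.stage_log,
        inputs={"tracks": str(tracks_path), "h2b": str(h2b_path) if h2b_path else None},
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def run_interactome_pipeline(
    config: PipelineConfig,
    protein_groups_path: str | Path,
    design: Mapping[str, str],
    out_dir: str | Path,
) -> RunManifest:
    """Run the differential-interactome caller on a protein-group table."""
    protein_groups_path = Path(protein_groups_path)
    if not protein_groups_path.exists():
        raise FileNotFoundError(f"protein-group table not found: {protein_groups_path}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix = read_protein_groups(protein_groups_path, design)
    result = differential_interactome(matrix, config.interactome)
    for stage, count in result.stage_log.items():
        log.info("interactome: %s = %d", stage, count)

    calls_path = out_dir / "interactor_calls.csv"
    result.calls.to_csv(calls_path, index=False)
    summ_path = out_dir / "interactome_summary.json"
    summ_path.write_text(
        json.dumps({"stage_log": result.stage_log}, indent=2) + "\n"
    )
    manifest = RunManifest(
        pipeline="interactome",
        config=_config_snapshot(config),
        seeds={"master": config.seed, "imputation": config.interactome.seed},
        stage_counts=result.stage_log,
        inputs={"protein_groups": str(protein_groups_path), "design": dict(design)},
        outputs=[str(calls_path), str(summ_path)],
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
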