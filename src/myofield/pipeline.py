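"""End-to-end orchestration: simulate, segment, score, summarize, test.

A run is described by a flat, module-namespaced configuration (YAML or
dict): one or more named conditions, each a synthetic scene or motion
specification plus a number of fields, followed by the quantification
stages and a group comparison across conditions.  Every default is
resolved into the manifest so a run is fully reproducible from the
manifest alone; identical config and seed give byte-identical result
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .localization import FieldLocalization, score_field, summarize_condition
from .motion import movement_index
from .puncta import detect_puncta, puncta_area_ratio
from .segmentation import segment_myotubes
from .stats import compare_groups
from .synth import (
    MotionSpec,
    SceneSpec,
    generate_contraction_sequence,
    generate_fluorescence_field,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "field_seed"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``conditions`` maps a condition name to ``{"n_fields": int, "scene":
    {...SceneSpec overrides...}}`` (localization/puncta modes) or
    ``{"n_fields": int, "motion": {...MotionSpec overrides...}}``
    (motion mode).
    """

    seed: int = 0
    outdir: str = "myofield_run"
    mode: str = "localization"  # "localization" | "puncta" | "motion"
    conditions: dict[str, dict[str, Any]] = field(default_factory=dict)
    control_condition: str | None = None
    segmentation: dict[str, Any] = field(
        default_factory=lambda: {"min_myotube_area": 500, "min_nucleus_area": 30,
                                 "smoothing_sigma": 2.0}
    )
    localization: dict[str, Any] = field(
        default_factory=lambda: {"k_sigma": 3.0, "min_blob_area": 50,
                                 "min_cyto_fraction": 0.02}
    )
    puncta: dict[str, Any] = field(
        default_factory=lambda: {"tophat_radius": 5, "min_size": 4, "max_size": 400,
                                 "mode": "puncta"}
    )
    stats: dict[str, Any] = field(
        default_factory=lambda: {"design": "auto", "posthoc": "tukey", "alpha": 0.05}
    )
    movement: dict[str, Any] = field(
        default_factory=lambda: {"lag": None, "noise_floor": 0.0, "stimulation_hz": None}
    )

    def __post_init__(self) -> None:
        if self.mode not in ("localization", "puncta", "motion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.control_condition is not None and self.control_condition not in self.conditions:
            raise ValueError(f"control_condition {self.control_condition!r} is not a condition")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        base = cls(seed=d.get("seed", 0), outdir=d.get("outdir", "myofield_run"),
                   mode=d.get("mode", "localization"), conditions=d["conditions"],
                   control_condition=d.get("control_condition"))
        for block in ("segmentation", "localization", "puncta", "stats", "movement"):
            getattr(base, block).update(d.get(block, {}))
        return base

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def resolved(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: RunConfig
    per_myotube: pd.DataFrame | None
    per_field: pd.DataFrame
    condition_summary: pd.DataFrame
    comparison: Any | None
    manifest: dict[str, Any]


def field_seed(base_seed: int, condition_index: int, field_index: int) -> int:
    """Stable per-field seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([int(base_seed), condition_index, field_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all requested stages and write CSVs, a manifest and a log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("myofield")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.mode == "motion":
            result = _run_motion(config, outdir)
        else:
            result = _run_fluorescence(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return result


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _comparison_tables(config: RunConfig, per_field: pd.DataFrame, metric: str):
    grouped = {name: sub[metric].to_numpy()
               for name, sub in per_field.groupby("condition", sort=True)}
    if len(grouped) < 2 or min(len(v) for v in grouped.values()) < 2:
        log.info("skipping group comparison: need >= 2 conditions with n >= 2 fields")
        return None
    return _stage("stats", compare_groups, grouped,
                  design=config.stats.get("design", "auto"),
                  posthoc=config.stats.get("posthoc", "tukey"),
                  control=config.control_condition,
                  alpha=config.stats.get("alpha", 0.05))


def _finalize(config, outdir, files, per_myotube, per_field, summary, comparison):
    if comparison is not None:
        files.append(_write(comparison.to_frame(), outdir / "comparisons.csv"))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(config=config, per_myotube=per_myotube, per_field=per_field,
                     condition_summary=summary, comparison=comparison, manifest=manifest)


def _run_fluorescence(config: RunConfig, outdir: Path) -> RunResult:
    seg, loc = config.segmentation, config.localization
    myotube_frames, field_rows, summary_rows = [], [], []
    for ci, (cond, block) in enumerate(sorted(config.conditions.items())):
        n_fields = int(block.get("n_fields", 1))
        scene_over = dict(block.get("scene", {}))
        fields: list[FieldLocalization] = []
        for fi in range(n_fields):
            spec = SceneSpec(**{**scene_over, "seed": field_seed(config.seed, ci, fi)})
            log.info("condition %s field %d: simulating (seed %d)", cond, fi, spec.seed)
            fieldobj, _truth = _stage("simulate", generate_fluorescence_field, spec)
            fieldobj.field_id = f"{cond}_f{fi}"
            if config.mode == "localization":
                fl = _stage("localize", score_field, fieldobj,
                            min_myotube_area=seg["min_myotube_area"],
                            min_nucleus_area=seg["min_nucleus_area"],
                            smoothing_sigma=seg["smoothing_sigma"],
                            k_sigma=loc["k_sigma"],
                            min_blob_area=loc["min_blob_area"],
                            min_cyto_fraction=loc["min_cyto_fraction"])
                df = fl.to_frame()
                df.insert(0, "condition", cond)
                myotube_frames.append(df)
                fields.append(fl)
                field_rows.append({
                    "condition": cond, "field_id": fieldobj.field_id,
                    "n_myotubes": len(fl.myotubes),
                    "accumulation_fraction": float(df["accumulation_flag"].mean()),
                    "mean_nuclear_positive_ratio": float(
                        df["nuclear_positive_ratio"].dropna().mean()),
                })
            else:  # puncta mode
                tubes = _stage("segment", segment_myotubes, fieldobj["structural"],
                               min_myotube_area=seg["min_myotube_area"],
                               smoothing_sigma=seg["smoothing_sigma"])
                _mask, comps = _stage("puncta", detect_puncta, fieldobj["marker"], tubes,
                                      tophat_radius=config.puncta["tophat_radius"],
                                      min_size=config.puncta["min_size"],
                                      max_size=config.puncta["max_size"],
                                      mode=config.puncta.get("mode", "puncta"))
                results, psummary = puncta_area_ratio(comps, tubes)
                df = pd.DataFrame([{
                    "condition": cond, "field_id": fieldobj.field_id,
                    "myotube_label": r.myotube_label, "myotube_area": r.myotube_area,
                    "puncta_area": r.puncta_area, "n_puncta": r.n_puncta,
                    "puncta_ratio": r.puncta_ratio,
                } for r in results])
                myotube_frames.append(df)
                field_rows.append({
                    "condition": cond, "field_id": fieldobj.field_id,
                    "n_myotubes": int(psummary["n_myotubes"].iloc[0]),
                    "mean_puncta_ratio": float(psummary["mean_puncta_ratio"].iloc[0]),
                })
        if config.mode == "localization" and fields:
            cs = summarize_condition(fields)
            summary_rows.append({"condition": cond, **dataclasses.asdict(cs)})

    per_myotube = pd.concat(myotube_frames, ignore_index=True)
    per_field = pd.DataFrame(field_rows)
    if config.mode == "puncta":
        summary = (per_field.groupby("condition", sort=True)["mean_puncta_ratio"]
                   .agg(["mean", "sem", "count"]).reset_index()
                   .rename(columns={"mean": "mean_puncta_ratio",
                                    "sem": "se_puncta_ratio", "count": "n_fields"}))
        metric = "mean_puncta_ratio"
    else:
        summary = pd.DataFrame(summary_rows)
        metric = "accumulation_fraction"
    files = [_write(per_myotube, outdir / "per_myotube.csv"),
             _write(per_field, outdir / "per_field.csv"),
             _write(summary, outdir / "condition_summary.csv")]
    comparison = _comparison_tables(config, per_field, metric)
    return _finalize(config, outdir, files, per_myotube, per_field, summary, comparison)


def _run_motion(config: RunConfig, outdir: Path) -> RunResult:
    rows = []
    for ci, (cond, block) in enumerate(sorted(config.conditions.items())):
        n_fields = int(block.get("n_fields", 3))
        motion_over = dict(block.get("motion", {}))
        for fi in range(n_fields):
            spec = MotionSpec(**{**motion_over, "seed": field_seed(config.seed, ci, fi)})
            log.info("condition %s field %d: simulating video (seed %d)", cond, fi, spec.seed)
            seq, _truth = _stage("simulate", generate_contraction_sequence, spec)
            res = _stage("movement-index", movement_index, seq,
                         lag=config.movement.get("lag"),
                         noise_floor=config.movement.get("noise_floor", 0.0),
                         stimulation_hz=config.movement.get("stimulation_hz"))
            rows.append({"condition": cond, "field_id": f"{cond}_f{fi}",
                         "movement_index": res.movement_index,
                         "n_pairs": res.n_pairs, "lag": res.lag})
    per_field = pd.DataFrame(rows)
    summary = (per_field.groupby("condition", sort=True)["movement_index"]
               .agg(["mean", "sem", "count"]).reset_index()
               .rename(columns={"mean": "mean_movement_index",
                                "sem": "se_movement_index", "count": "n_fields"}))
    files = [_write(per_field, outdir / "per_field.csv"),
             _write(summary, outdir / "condition_summary.csv")]
    comparison = _comparison_tables(config, per_field, "movement_index")
    return _finalize(config, outdir, files, None, per_field, summary, comparison)
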