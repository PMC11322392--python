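"""End-to-end driver: simulate -> track -> curves -> areas -> statistics.

A :class:`PipelineConfig` bundles the stage configurations and a master
seed; :func:`run_pipeline` executes every stage, writes each stage's
outputs under the configured directory, and returns a
:class:`RunManifest` with seeds and per-artifact checksums so a rerun
with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import MUSCLES, ConfigError
from .curve_areas import build_feature_table, decompose
from .deformation_curves import analyzed_segment
from .io import (write_curves, write_feature_table, write_ground_truth,
                 write_sequence, write_tracked_roi)
from .multivariate_stats import crossvalidate_jackknife, fit_pca, loading_table
from .speckle_tracking import TrackingConfig, place_roi, track_sequence
from .synth_cohort import (CohortConfig, MotionModel, SceneConfig,
                           simulate_cohort)
from .univariate_stats import (mixed_anova, posthoc_level_contrasts,
                               results_frame)
from .core import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

#: ROI placement: layer mid-depths (mm) of the default phantom geometry.
DEFAULT_ROI_DEPTHS = {"TR": 5.0, "SP": 12.0, "Scap": 19.0,
                      "Scerv": 26.0, "MF": 33.0}


@dataclass
class PipelineConfig:
    """All knobs of one reproducible pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    motion: MotionModel = field(default_factory=MotionModel)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    analyzed_cycle: int = 10
    roi_length_mm: float = 15.0
    roi_depths_mm: dict = field(default_factory=lambda: dict(DEFAULT_ROI_DEPTHS))
    alpha: float = 0.05
    dv: str = "total"
    n_orthogonal: int = 1
    cv_folds: int = 7
    write_videos: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(config_to_dict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # YAML-friendly: tuples to lists handled by asdict/safe_dump already
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj
    d["cohort"]["group_effects"] = {
        "|".join(k): v for k, v in cfg.cohort.group_effects.items()}
    d["cohort"]["followup_effects"] = {
        "|".join(k) if isinstance(k, tuple) else k: v
        for k, v in cfg.cohort.followup_effects.items()}
    return clean(d)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    scene = d.pop("scene", {})
    motion = d.pop("motion", {})
    cohort = dict(d.pop("cohort", {}))
    tracking = d.pop("tracking", {})
    for key in ("image_size", "pixel_spacing_mm"):
        if key in scene:
            scene[key] = tuple(scene[key])
    for key in ("sway_mm",):
        if key in motion:
            motion[key] = tuple(motion[key])
    if "group_effects" in cohort:
        cohort["group_effects"] = {tuple(k.split("|")): v
                                   for k, v in cohort["group_effects"].items()}
    if "followup_effects" in cohort:
        cohort["followup_effects"] = {
            tuple(k.split("|")) if "|" in k else k: v
            for k, v in cohort["followup_effects"].items()}
    for key in ("timepoints", "directions", "groups"):
        if key in cohort:
            cohort[key] = tuple(cohort[key])
    return PipelineConfig(scene=SceneConfig(**scene),
                          motion=MotionModel(**motion),
                          cohort=CohortConfig(**cohort),
                          tracking=TrackingConfig(**tracking), **d)


@dataclass
class RunManifest:
    """Record of one pipeline run: versions, seeds, artifact checksums."""

    version: str
    config_sha256: str
    seed: int
    started: str
    finished: str = ""
    checksums: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def add(self, path: Path) -> None:
        self.checksums[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage end to end and write all artifacts.

    Stage failures abort with the stage name and offending subject in the
    exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = config.to_yaml(out / "config.yaml")
    manifest = RunManifest(
        version=__version__,
        config_sha256=hashlib.sha256(cfg_yaml.read_bytes()).hexdigest(),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.add(cfg_yaml)

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    scene = dataclasses.replace(config.scene, seed=config.seed)

    logger.info("simulating cohort: %d per group", cohort_cfg.n_per_group)
    sims = simulate_cohort(cohort_cfg, scene, config.motion)

    records = []
    half = config.roi_length_mm / 2.0
    for sim in sims:
        rec = sim.record
        for direction, (seq, truth) in sim.sequences.items():
            tag = f"{rec.subject}_{rec.timepoint}_{direction}"
            try:
                if config.write_videos:
                    manifest.add(write_sequence(seq, out / "videos" / f"{tag}.tif"))
                    manifest.add(write_ground_truth(
                        truth, out / "truth" / f"{tag}.csv"))
                muscles = {}
                for m in MUSCLES:
                    depth = config.roi_depths_mm[m]
                    roi = place_roi(seq, m,
                                    (depth, truth.center_lateral_mm - half),
                                    (depth, truth.center_lateral_mm + half),
                                    config=config.tracking)
                    tracked = track_sequence(seq, roi, config.tracking)
                    manifest.add(write_tracked_roi(
                        tracked, out / "tracking" / f"{tag}_{m}.csv"))
                    curve, rate = analyzed_segment(
                        tracked, seq, cycle_index=config.analyzed_cycle,
                        direction=direction)
                    manifest.add(write_curves(
                        curve, rate, out / "curves" / f"{tag}_{m}.csv"))
                    muscles[m] = decompose(curve, rate)
            except Exception as exc:
                raise RuntimeError(
                    f"stage tracking/curves failed for subject {tag}") from exc
            records.append({"subject": rec.subject, "group": rec.group,
                            "sex": rec.sex, "age": rec.age,
                            "wad_grade": rec.wad_grade,
                            "timepoint": rec.timepoint,
                            "direction": direction, "muscles": muscles})

    table = build_feature_table(records)
    manifest.add(write_feature_table(table, out / "feature_table.csv"))

    for direction in config.cohort.directions:
        sub = table[(table["direction"] == direction)
                    & (table["timepoint"] == config.cohort.timepoints[0])]
        sub = sub.reset_index(drop=True)
        try:
            anova = results_frame(mixed_anova(sub, dv=config.dv))
            contrasts = posthoc_level_contrasts(sub, dv=config.dv)
            anova_path = out / f"anova_{direction}.csv"
            anova.to_csv(anova_path, index=False)
            manifest.add(anova_path)
            cpath = out / f"contrasts_{direction}.csv"
            import pandas as pd
            pd.DataFrame([c.__dict__ for c in contrasts]).to_csv(cpath, index=False)
            manifest.add(cpath)

            X = sub[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
            pca = fit_pca(X, n_components=2)
            scores_path = out / f"pca_scores_{direction}.csv"
            pd.DataFrame(pca.scores, columns=["PC1", "PC2"]).assign(
                group=sub["group"].to_numpy()).to_csv(scores_path, index=False)
            manifest.add(scores_path)
            model = crossvalidate_jackknife(
                X, sub["group"].to_numpy(), n_orthogonal=config.n_orthogonal,
                n_folds=config.cv_folds, seed=config.seed)
            lt = loading_table(model, list(FEATURE_COLUMNS))
            lpath = out / f"oplsda_loadings_{direction}.csv"
            lt.to_csv(lpath, index=False)
            manifest.add(lpath)
            manifest.log.append(
                {"direction": direction,
                 "oplsda_cv_accuracy": model.cv_accuracy})
        except Exception as exc:
            raise RuntimeError(
                f"stage statistics failed for direction {direction}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest


def demo_config(out_dir: str = "pipeline_out", seed: int = 0) -> PipelineConfig:
    """A minutes-scale demonstration config: 4 subjects per group, small
    frames, three rotation cycles (the third is analyzed)."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        scene=SceneConfig(image_size=(120, 110),
                          pixel_spacing_mm=(0.33, 0.35),
                          frame_rate_hz=25.0, seed=seed),
        motion=MotionModel(n_cycles=3, rest_frames=5),
        cohort=CohortConfig(n_per_group=4, seed=seed),
        analyzed_cycle=3,
        roi_depths_mm={m: d * 39.6 / 40.0 for m, d in DEFAULT_ROI_DEPTHS.items()},
        cv_folds=4,
        write_videos=True,
    )
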