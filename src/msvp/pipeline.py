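"""Pipeline orchestration: config validation, stage execution, reports.

One config drives the whole chain (simulate or read samples, preprocess,
group time course, leave-one-out detection, optional bootstrap power); all
tabular outputs are deterministic TSVs and a manifest records the config
hash, seed and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as msvp_io
from .detection import DetectionResults, default_windows, run_loo_detection, WindowSpec
from .power import BootstrapPower, HitRule, PowerCurve
from .preprocess import (AccuracyReport, Epochs, QCReport, preprocess,
                         score_accuracy, MEASURES)
from .simulate import SimConfig, default_config, simulate_dataset
from .timecourse import TimecourseResults, run_timecourse

logger = logging.getLogger("msvp")

_SCHEMA: Dict[str, tuple] = {
    "samples": ("path",),
    "output_dir": ("path",),
    "seed": ("int",),
    "simulate": ("dict",),
    "preprocess": ("dict",),
    "model": ("dict",),
    "detection": ("dict",),
    "power": ("dict",),
}

_SECTION_KEYS = {
    "preprocess": {"pool_participants", "accuracy_threshold_px"},
    "model": {"structure", "grid_step_ms", "fdr_q", "min_cluster_ms",
              "covariate_gaze", "measures"},
    "detection": {"alpha", "orienting_direction"},
    "power": {"enabled", "candidate_ns", "n_iterations", "alpha",
              "min_consecutive_ms", "strict", "grid_step_ms"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; defaults are the study's choices."""

    output_dir: str = "msvp_out"
    seed: int = 0
    samples: Optional[str] = None
    simulate: Dict = field(default_factory=dict)
    preprocess: Dict = field(default_factory=dict)
    model: Dict = field(default_factory=dict)
    detection: Dict = field(default_factory=dict)
    power: Dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            extra = set(raw.get(section, {}) or {}) - allowed
            if extra:
                raise ValueError(
                    f"unknown keys in config section {section!r}: {sorted(extra)}"
                )
        return cls(**{k: v for k, v in raw.items() if v is not None})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "samples": self.samples,
            "simulate": self.simulate,
            "preprocess": self.preprocess,
            "model": self.model,
            "detection": self.detection,
            "power": self.power,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ArtifactBundle:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    epochs: Epochs
    qc: QCReport
    accuracy: AccuracyReport
    timecourses: Dict[str, TimecourseResults]
    detections: Dict[str, DetectionResults]
    power: Optional[PowerCurve] = None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: PipelineConfig) -> ArtifactBundle:
    """Execute every stage and write the artifact TSVs plus a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    stage = "input"
    try:
        if config.samples:
            table = msvp_io.read_samples(config.samples)
            logger.info("read %d sample rows from %s", len(table), config.samples)
        else:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            gaze_mode = sim.pop("gaze_mode", "constrained")
            n_participants = sim.pop("n_participants", 29)
            sim_cfg = default_config(gaze_mode=gaze_mode,
                                     n_participants=n_participants,
                                     seed=sim.pop("seed"))
            if sim:
                merged = sim_cfg.to_dict()
                for key, val in sim.items():
                    if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
                        merged[key] = {**merged[key], **val}
                    else:
                        merged[key] = val
                sim_cfg = SimConfig.from_dict(merged)
            table = simulate_dataset(sim_cfg)
            logger.info("simulated %d sample rows (%s design)", len(table), gaze_mode)

        stage = "preprocess"
        epochs, qc = preprocess(
            table, pool_participants=config.preprocess.get("pool_participants", False)
        )
        logger.info("epoched %d trials; %d excluded by baseline QC",
                    qc.n_total_trials, qc.n_excluded)
        for _, row in qc.excluded.iterrows():
            logger.info("  excluded trial %s/%s: %s", row["participant_id"],
                        row["trial_index"], row["reason"])
        accuracy = score_accuracy(
            epochs,
            threshold_px=config.preprocess.get("accuracy_threshold_px", 50.0),
        )

        stage = "timecourse"
        model_opts = dict(config.model)
        measures = model_opts.pop("measures", list(MEASURES))
        fit_kwargs = {
            "structure": model_opts.get("structure", "slopes"),
            "grid_step_ms": model_opts.get("grid_step_ms", 10),
            "q": model_opts.get("fdr_q", 0.05),
            "min_cluster_ms": model_opts.get("min_cluster_ms", 200),
        }
        covariate = model_opts.get("covariate_gaze", False)
        timecourses = {}
        for measure in measures:
            timecourses[measure] = run_timecourse(
                epochs, measure, covariate_gaze=covariate, **fit_kwargs
            )
            n_nc = int((~timecourses[measure].frame["converged"]).sum())
            logger.info("timecourse %s: %d clusters, %d non-converged rows",
                        measure, len(timecourses[measure].clusters), n_nc)

        stage = "detection"
        alpha = config.detection.get("alpha", 0.05)
        orient = int(config.detection.get("orienting_direction", +1))
        detections = {}
        for measure in measures:
            windows = default_windows(measure)
            if measure == "gaze_signed" and orient == -1:
                windows = [
                    WindowSpec(w.measure, w.start_ms, w.stop_ms, -w.direction, w.label)
                    for w in windows
                ]
            detections[measure] = run_loo_detection(
                epochs, measure, windows=windows, alpha=alpha
            )

        stage = "power"
        power = None
        pw = dict(config.power)
        if pw.get("enabled", False):
            rule = HitRule(alpha=pw.get("alpha", 0.05),
                           min_consecutive_ms=pw.get("min_consecutive_ms", 200),
                           strict=pw.get("strict", True))
            power = BootstrapPower(
                epochs, rule=rule,
                grid_step_ms=pw.get("grid_step_ms", 10),
            ).run(
                pw.get("candidate_ns", [5, 10, 15, 20, 25, 30]),
                n_iterations=pw.get("n_iterations", 1000),
                seed=config.seed,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = ArtifactBundle(config=config, epochs=epochs, qc=qc,
                            accuracy=accuracy, timecourses=timecourses,
                            detections=detections, power=power)
    write_bundle(bundle, out)
    return bundle


def write_bundle(bundle: ArtifactBundle, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.qc.excluded, out / "qc_excluded.tsv")
    _write_tsv(bundle.qc.per_participant, out / "qc_participants.tsv")
    acc = bundle.accuracy.per_participant.reset_index()
    _write_tsv(acc, out / "accuracy.tsv")
    cluster_frames = []
    for measure, tc in sorted(bundle.timecourses.items()):
        _write_tsv(
            tc.frame[["time_ms", "contrast", "beta", "se", "p_raw", "p_fdr",
                      "converged", "n_obs"]],
            out / f"timecourse_{measure}.tsv",
        )
        cluster_frames.append(tc.cluster_frame())
    if cluster_frames:
        _write_tsv(pd.concat(cluster_frames, ignore_index=True),
                   out / "clusters.tsv")
    det_frames = [d.to_frame() for d in bundle.detections.values()]
    if det_frames:
        _write_tsv(pd.concat(det_frames, ignore_index=True),
                   out / "detections.tsv")
        _write_tsv(
            pd.concat([d.summary_frame() for d in bundle.detections.values()],
                      ignore_index=True),
            out / "detection_summary.tsv",
        )
    if bundle.power is not None:
        _write_tsv(bundle.power.frame, out / "power.tsv")

    import importlib.metadata as md

    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "statsmodels"):
        try:
            versions[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            versions[pkg] = "unknown"
    manifest = {
        "config": bundle.config.to_dict(),
        "config_hash": bundle.config.config_hash(),
        "seed": bundle.config.seed,
        "versions": versions,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    (out / "report.md").write_text(make_report(bundle))


def make_report(bundle: ArtifactBundle) -> str:
    """Deterministic human-readable summary of one pipeline run."""
    lines = ["# MSVP analysis report", ""]
    lines.append("## Preprocessing")
    lines.append(
        f"- trials epoched: {bundle.qc.n_total_trials}; "
        f"excluded by baseline QC: {bundle.qc.n_excluded}"
    )
    lines.append(f"- behavioural scoring rule: {bundle.accuracy.rule}")
    means = bundle.accuracy.condition_means()
    for cond in sorted(means.index):
        lines.append(f"  - accuracy {cond}: {100.0 * means[cond]:.1f}%")
    lines.append("")
    lines.append("## Group time course")
    for measure, tc in sorted(bundle.timecourses.items()):
        lines.append(tc.summary())
    lines.append("")
    lines.append("## Individual leave-one-out detection")
    any_det = False
    for measure, det in sorted(bundle.detections.items()):
        lines.append(det.summary())
        any_det = any_det or bool(det.detections)
    if not any_det:
        lines.append("no participants tested")
    if bundle.power is not None:
        lines.append("")
        lines.append("## Bootstrap power")
        lines.append(bundle.power.summary())
    lines.append("")
    return "\n".join(lines)
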