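"""End-to-end orchestration: simulate/load -> preprocess -> features -> stats.

:func:`run_full` composes the stages deterministically and writes an
artifact bundle (features CSV, correlation report CSV + JSON, and a JSON
run manifest recording the config hash, seed, package version and
per-stage subject accounting so exclusions are auditable). Running the
stages separately through the CLI with intermediate files produces
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import correlation_table
from .errors import FeatureUndefinedError, PipelineError, VolsenseError
from .features import FeatureConfig, extract_features
from .io_formats import (
    read_recording_log,
    read_scales,
    write_correlation_report,
    write_feature_table,
    write_recording_log,
    write_scales,
)
from .preprocessing import preprocess
from .synthetic import SimulationParams, ground_truth_frame, simulate_cohort
from .types import FEATURES, FeatureRow, RecordingLog, SubjectScales

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults mirror the study protocol: 14 days at a 5-minute period
    (4032 expected recordings), 24-hour autocorrelation lag, 00:00–06:00
    sleep window, 3-SD clipping, 50% sufficiency threshold, screening
    cutoffs LSAS>=60 / GAD-7>=10 / PHQ-8>=10, exit-timepoint scores.
    """

    features: FeatureConfig = field(default_factory=FeatureConfig)
    timepoint: str = "exit"
    adjust: str | None = None
    simulation: SimulationParams | None = None
    recordings_path: str | None = None
    scales_path: str | None = None

    def to_dict(self) -> dict:
        d = {
            "features": asdict(self.features),
            "timepoint": self.timepoint,
            "adjust": self.adjust,
            "recordings_path": self.recordings_path,
            "scales_path": self.scales_path,
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


def cohort_features(
    logs: dict[str, RecordingLog], config: FeatureConfig = FeatureConfig()
) -> list[FeatureRow]:
    """Extract the feature row for every subject (in sorted id order)."""
    rows = []
    for sid in sorted(logs):
        try:
            series = preprocess(logs[sid], config.period_min, config.clip_k)
        except FeatureUndefinedError:
            series = None
        rows.append(extract_features(logs[sid], series, config))
    return rows


def run_cohort(
    logs: dict[str, RecordingLog],
    scales: list[SubjectScales],
    config: RunConfig = RunConfig(),
):
    """Features + correlation report + accounting for an in-memory cohort."""
    rows = cohort_features(logs, config.features)
    report = correlation_table(rows, scales, config.timepoint, config.adjust)
    manifest = {
        "subjects_in": len(rows),
        "included": sum(1 for r in rows if r.included),
        "excluded_insufficient_data": sum(1 for r in rows if not r.included),
        "analyzed": max(report[k].n for k in report),
    }
    return rows, report, manifest


def run_full(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the artifact bundle under ``out_dir``.

    Returns the run manifest. Any stage failure is re-raised as a
    :class:`PipelineError` tagged with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        try:
            logs, scales, truths = simulate_cohort(config.simulation)
        except VolsenseError as e:
            raise PipelineError("simulate", str(e)) from e
        write_recording_log(logs, out / "recordings.csv")
        write_scales(scales, out / "scales.csv")
        ground_truth_frame(truths).to_csv(out / "ground_truth.csv", index=False)
    elif config.recordings_path and config.scales_path:
        try:
            logs = read_recording_log(config.recordings_path)
            scales = read_scales(config.scales_path)
        except VolsenseError as e:
            raise PipelineError("read", str(e)) from e
    else:
        raise PipelineError(
            "config", "need either simulation params or recordings+scales paths"
        )

    try:
        rows = cohort_features(logs, config.features)
    except VolsenseError as e:
        raise PipelineError("extract-features", str(e)) from e
    write_feature_table(rows, out / "features.csv")

    try:
        report = correlation_table(rows, scales, config.timepoint, config.adjust)
    except VolsenseError as e:
        raise PipelineError("analyze", str(e)) from e
    write_correlation_report(report, out / "report.csv", "csv")
    write_correlation_report(report, out / "report.json", "json")

    cfg = config.to_dict()
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": None if config.simulation is None else config.simulation.seed,
        "counts": {
            "subjects_in": len(rows),
            "included": sum(1 for r in rows if r.included),
            "excluded_insufficient_data": sum(1 for r in rows if not r.included),
            "analyzed": max(report[k].n for k in report),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def summarize_features(rows: list[FeatureRow]) -> pd.DataFrame:
    """Descriptive statistics table for included subjects' features.

    Columns: mean, sd (sample SD), min, q1, q2, q3, max per feature, with
    quartiles by linear interpolation between order statistics.
    """
    included = [r for r in rows if r.included]
    if not included:
        raise VolsenseError("no included rows to summarize")
    records = []
    for feat in FEATURES:
        vals = np.array(
            [r.get(feat) for r in included if r.get(feat) is not None], dtype=float
        )
        if len(vals) == 0:
            raise VolsenseError(f"feature {feat} has no defined values")
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        records.append(
            {
                "feature": feat,
                "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "min": vals.min(),
                "q1": q1,
                "q2": q2,
                "q3": q3,
                "max": vals.max(),
            }
        )
    return pd.DataFrame(records)
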