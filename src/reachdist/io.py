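"""File formats, run configuration and the end-to-end analysis pipeline.

Trials travel as long-format CSV (one row per sample) in either of two
dialects: a landmark dialect with 3-D shoulder/elbow/wrist coordinates in
cm, or an angle dialect with a precomputed elbow angle in degrees (and
optionally a forearm speed in cm/s). Mixture models and provenance are
serialized as JSON. All indices are 0-based, times in seconds, angles in
degrees.

``run_pipeline`` ties the stages together: segment -> normalize -> fit ->
distances (stroke vs. control references, control leave-one-out) ->
kinematics, with full determinism under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divergence import METRICS, nearest_neighbor_distance
from .gmm import MixtureModel, select_gmm
from .kinematics import summarize_participant_target
from .normalize import build_model_set
from .preprocess import (
    LandmarkSeries,
    ParameterError,
    SegmentationError,
    Trial,
    segment_trial,
    trial_from_landmarks,
)
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger("reachdist")

SCHEMA_VERSION = 1

_META_COLS = ["participant_id", "group", "target", "trial_id", "t"]
_LANDMARK_COLS = [
    f"{lm}_{ax}" for lm in ("shoulder", "elbow", "wrist") for ax in "xyz"
]
_ANGLE_COLS = ["elbow_angle_deg"]


class SchemaError(ValueError):
    """An input file does not match either supported CSV dialect."""


@dataclass
class RunConfig:
    """All tunable parameters of the full pipeline."""

    fs: float = 120.0
    cutoff: float = 6.0
    filter_order: int = 3
    frac: float = 0.1
    hold: float = 0.1
    bandwidth_mult: float = 2.0
    kmin: int = 2
    kmax: int = 25
    em_tol: float = 1e-3
    em_max_iter: int = 150
    em_reg: float = 1e-6
    bic_patience: int | None = 4
    metrics: tuple[str, ...] = ("HD", "BKLD", "logBKLD")
    kappa: float = 1.0
    leave_one_out: bool = True
    circular_velocity: bool = True
    seed: int = 0
    cohort: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.cutoff <= 0 or self.fs <= 2 * self.cutoff:
            raise ParameterError("require fs > 2 * cutoff > 0")
        if not 0 < self.frac < 1 or self.hold <= 0:
            raise ParameterError("require 0 < frac < 1 and hold > 0")
        if self.kmin < 1 or self.kmax < self.kmin:
            raise ParameterError(f"invalid order range [{self.kmin}, {self.kmax}]")
        if self.bandwidth_mult <= 0:
            raise ParameterError("bandwidth_mult must be positive")
        if self.em_tol <= 0 or self.em_max_iter < 1 or self.em_reg < 0:
            raise ParameterError("invalid EM settings")
        if self.bic_patience is not None and self.bic_patience < 1:
            raise ParameterError("bic_patience must be >= 1 or None")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ParameterError(f"unknown metrics {unknown}")


@dataclass
class PipelineResult:
    """Outputs of one full pipeline run."""

    distances: pd.DataFrame
    kinematics: pd.DataFrame
    models: list[MixtureModel]
    provenance: dict


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """Serialize trials to the long-format angle-dialect CSV schema."""
    frames = []
    for tr in trials:
        n = len(tr)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "group": tr.group,
                    "target": tr.target,
                    "trial_id": tr.trial_id,
                    "t": np.arange(n) / tr.fs,
                    "elbow_angle_deg": tr.angle,
                    "speed_cm_s": tr.speed,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trials_csv(trials: list[Trial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.10g")


def _infer_fs(t: np.ndarray, fs: float | None) -> float:
    if fs is not None:
        return fs
    dt = np.median(np.diff(t))
    if not np.isfinite(dt) or dt <= 0:
        raise SchemaError("cannot infer sampling rate from time column")
    return float(1.0 / dt)


def read_trials(
    path: str | Path, fs: float | None = None
) -> list[Trial] | list[LandmarkSeries]:
    """Read a trials CSV in either dialect; malformed rows are skipped.

    Returns ``LandmarkSeries`` records for the landmark dialect and
    ``Trial`` records for the angle dialect. If the angle dialect has no
    speed column, the forearm speed is derived from the angle derivative.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty file")
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"{path}: missing mandatory columns {missing_meta}")
    if set(_LANDMARK_COLS) <= set(df.columns):
        value_cols = _LANDMARK_COLS
        dialect = "landmarks"
    elif set(_ANGLE_COLS) <= set(df.columns):
        value_cols = _ANGLE_COLS + (
            ["speed_cm_s"] if "speed_cm_s" in df.columns else []
        )
        dialect = "angles"
    else:
        raise SchemaError(
            f"{path}: need either landmark columns {_LANDMARK_COLS} "
            f"or angle column {_ANGLE_COLS}"
        )

    numeric = ["t"] + value_cols
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df[numeric].notna().all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
    df = df[ok]
    if df.empty:
        raise SchemaError(f"{path}: no valid rows")

    records: list = []
    keys = ["participant_id", "group", "target", "trial_id"]
    for (pid, group, target, trial_id), g in df.groupby(keys, sort=True):
        g = g.sort_values("t")
        t = g["t"].to_numpy()
        trial_fs = _infer_fs(t, fs)
        if dialect == "landmarks":
            records.append(
                LandmarkSeries(
                    participant_id=str(pid),
                    target=str(target),
                    trial_id=str(trial_id),
                    fs=trial_fs,
                    shoulder=g[["shoulder_x", "shoulder_y", "shoulder_z"]].to_numpy(),
                    elbow=g[["elbow_x", "elbow_y", "elbow_z"]].to_numpy(),
                    wrist=g[["wrist_x", "wrist_y", "wrist_z"]].to_numpy(),
                )
            )
        else:
            angle = g["elbow_angle_deg"].to_numpy()
            if "speed_cm_s" in g.columns:
                speed = g["speed_cm_s"].to_numpy()
            else:
                from .preprocess import FOREARM_LEVER_CM, differentiate

                logger.info("deriving speed from angle for trial %s", trial_id)
                speed = np.abs(differentiate(angle, trial_fs)) * (
                    FOREARM_LEVER_CM * np.pi / 180.0
                )
            records.append(
                Trial(
                    participant_id=str(pid),
                    target=str(target),
                    trial_id=str(trial_id),
                    fs=trial_fs,
                    angle=angle,
                    speed=speed,
                    group=str(group),
                )
            )
    return records


def write_models_json(models: list[MixtureModel], path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "models": [m.to_dict() for m in models]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_models_json(path: str | Path) -> list[MixtureModel]:
    payload = json.loads(Path(path).read_text())
    return [MixtureModel.from_dict(d) for d in payload["models"]]


def run_pipeline(cfg: RunConfig, trials: list[Trial] | None = None) -> PipelineResult:
    """Run segment -> normalize -> fit -> distances -> kinematics.

    With no input trials, a synthetic cohort is generated from
    ``cfg.cohort`` (or the default cohort seeded by ``cfg.seed``). Distances
    are computed per target: stroke subjects against the control reference
    models, and controls against the other controls (leave-one-out).
    """
    if trials is None:
        cohort = cfg.cohort or CohortConfig(seed=cfg.seed, fs=cfg.fs)
        logger.info("simulating cohort (seed %d)", cohort.seed)
        trials = simulate_cohort(cohort)

    segmented: list[Trial] = []
    n_failed = 0
    for tr in trials:
        if isinstance(tr, LandmarkSeries):
            tr = trial_from_landmarks(tr, cutoff=cfg.cutoff, order=cfg.filter_order)
        try:
            segmented.append(
                segment_trial(
                    tr, cutoff=cfg.cutoff, order=cfg.filter_order,
                    frac=cfg.frac, hold=cfg.hold,
                )
            )
        except SegmentationError as exc:
            n_failed += 1
            logger.info("segmentation failed for %s/%s/%s: %s",
                        tr.participant_id, tr.target, tr.trial_id, exc)
    if not segmented:
        raise SegmentationError("pipeline aborted at segmentation: no analyzable trials")

    by_model: dict[tuple[str, str], list[Trial]] = {}
    for tr in segmented:
        by_model.setdefault((tr.participant_id, tr.target), []).append(tr)

    models: list[MixtureModel] = []
    summaries = []
    for (pid, target) in sorted(by_model):
        group_trials = by_model[(pid, target)]
        mset = build_model_set(group_trials, bandwidth_mult=cfg.bandwidth_mult)
        model = select_gmm(
            mset.points, kmin=cfg.kmin, kmax=cfg.kmax, seed=cfg.seed,
            tol=cfg.em_tol, max_iter=cfg.em_max_iter, reg=cfg.em_reg,
            patience=cfg.bic_patience,
            participant_id=pid, target=target, group=group_trials[0].group,
        )
        models.append(model)
        summaries.append(
            summarize_participant_target(
                group_trials, hold=cfg.hold, circular_velocity=cfg.circular_velocity
            )
        )

    dist_rows = []
    targets = sorted({m.target for m in models})
    for target in targets:
        refs = [m for m in models if m.target == target and m.group == "control"]
        subjects = [m for m in models if m.target == target]
        if not refs:
            logger.warning("no control reference models for target %s", target)
            continue
        for subj in subjects:
            if subj.group == "control" and not cfg.leave_one_out:
                continue
            for metric in cfg.metrics:
                try:
                    res = nearest_neighbor_distance(
                        subj, refs, metric, kappa=cfg.kappa, exclude_self=True
                    )
                except ParameterError as exc:
                    logger.warning("distance failed for %s/%s: %s",
                                   subj.participant_id, target, exc)
                    continue
                dist_rows.append(
                    {
                        "participant_id": subj.participant_id,
                        "group": subj.group,
                        "target": target,
                        "metric": metric,
                        "value": res.value,
                        "nearest_ref": res.nearest_ref_id,
                        "n_refs": len(res.all_ref_values),
                    }
                )

    distances = pd.DataFrame(dist_rows)
    kin_rows = [
        {
            "participant_id": s.participant_id,
            "group": s.group,
            "target": s.target,
            "movement_time_s": s.movement_time,
            "final_angle_deg": s.final_angle,
            "mean_velocity_deg_s": s.mean_velocity,
            "peak_velocity_deg_s": s.peak_velocity,
            "n_velocity_peaks": s.n_velocity_peaks,
            "n_trials": s.n_trials,
        }
        for s in summaries
    ]
    kinematics = pd.DataFrame(kin_rows)

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {
            k: v for k, v in asdict(cfg).items() if k != "cohort"
        },
        "n_input_trials": len(trials),
        "n_segmented_trials": len(segmented),
        "n_segmentation_failures": n_failed,
        "n_models": len(models),
        "model_orders": {
            f"{m.participant_id}/{m.target}": m.K for m in models
        },
    }
    return PipelineResult(
        distances=distances, kinematics=kinematics, models=models, provenance=provenance
    )


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write distances.csv, kinematics.csv, models.json and provenance.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.distances.to_csv(out / "distances.csv", index=False, float_format="%.10g")
    result.kinematics.to_csv(out / "kinematics.csv", index=False, float_format="%.10g")
    write_models_json(result.models, out / "models.json")
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True)
    )
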