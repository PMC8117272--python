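"""Spatiotemporal normalization of segmented trials for mixture modeling.

The time and angle dimensions of reach trajectories differ in magnitude by
orders of magnitude; modeling them jointly without rescaling would let the
larger-valued dimension dominate the fit. Each participant-by-target set of
trials is therefore pooled into a common frame: per-trial time is expressed
in units of the set's mean movement duration, every trajectory is resampled
to a constant per-set length with Gaussian-kernel (GRNN / Nadaraya-Watson)
regression, and both dimensions are min-max scaled to [-1, 1] using pooled
across-trial extrema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import ParameterError, Trial

logger = logging.getLogger("reachdist")


class DegenerateRangeError(ValueError):
    """A dimension has zero range, so min-max scaling is undefined."""


@dataclass
class ScaleParams:
    """Linear map from an original dimension onto [-1, 1]."""

    dim: str  # "time" or "angle"
    min_val: float
    max_val: float
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.max_val > self.min_val:
            raise DegenerateRangeError(
                f"{self.dim}: max ({self.max_val}) must exceed min ({self.min_val})"
            )

    def scale(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        span = self.max_val - self.min_val
        return self.lo + (self.hi - self.lo) * (x - self.min_val) / span

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        y = np.asarray(scaled, dtype=float)
        span = self.max_val - self.min_val
        return self.min_val + (y - self.lo) * span / (self.hi - self.lo)


@dataclass
class ModelInputSet:
    """Pooled, scaled, constant-length point set for one participant x target.

    ``points`` has shape (n_trials * n_samples, 2) with columns
    (scaled time, scaled angle), each within [-1, 1].
    """

    participant_id: str
    target: str
    n_samples: int
    points: np.ndarray
    scale_params: dict[str, ScaleParams]
    n_trials: int
    group: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError(f"points must be (n, 2), got {self.points.shape}")
        if self.n_samples < 2:
            raise ParameterError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.points.shape[0] != self.n_trials * self.n_samples:
            raise ParameterError(
                f"point count {self.points.shape[0]} != "
                f"n_trials ({self.n_trials}) x n_samples ({self.n_samples})"
            )
        if np.any(np.abs(self.points) > 1.0 + 1e-9):
            raise ParameterError("scaled points must lie within [-1, 1]^2")


def minmax_scale(values: np.ndarray, params: ScaleParams) -> np.ndarray:
    """Scale values linearly so that [min_val, max_val] maps onto [-1, 1]."""
    return params.scale(values)


def grnn_regress(
    train_t: np.ndarray,
    train_y: np.ndarray,
    query_t: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Gaussian-kernel regression (general regression neural network).

    yhat(t) = sum_i y_i K(t - t_i) / sum_i K(t - t_i) with a Gaussian kernel
    of width ``bandwidth``. The estimate is a convex combination of the
    training values, so it stays within [min(train_y), max(train_y)].
    Weights are formed in log-space for numerical safety at queries far from
    the training support.
    """
    t = np.asarray(train_t, dtype=float)
    y = np.asarray(train_y, dtype=float)
    q = np.asarray(query_t, dtype=float)
    if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
        raise ParameterError("train_t and train_y must be equal-length 1-D arrays")
    if t.size < 2:
        raise ParameterError("need at least two training points")
    if bandwidth <= 0:
        raise ParameterError(f"bandwidth must be positive, got {bandwidth}")
    # (m, n) matrix of log kernel weights
    logw = -0.5 * ((q[:, None] - t[None, :]) / bandwidth) ** 2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return (w @ y) / w.sum(axis=1)


def build_model_set(
    trials: list[Trial],
    bandwidth_mult: float = 2.0,
) -> ModelInputSet:
    """Pool, resample and scale a participant-by-target set of trials.

    The per-set resampling count is round(mean segmented duration x fs).
    Each trial's angle-versus-time function is approximated by Gaussian
    kernel regression (bandwidth = ``bandwidth_mult`` x the mean spacing of
    that trial's time samples) and evaluated on a uniform grid over the
    trial's own segment, so duration differences between trials survive in
    the scaled frame. Time is first expressed in units of the mean movement
    duration; both dimensions are then min-max scaled to [-1, 1] using
    extrema pooled across trials.
    """
    valid: list[Trial] = []
    for tr in trials:
        if tr.discarded:
            logger.info("skipping discarded trial %s: %s", tr.trial_id, tr.discard_reason)
            continue
        if not tr.segmented:
            logger.warning("skipping unsegmented trial %s", tr.trial_id)
            continue
        if tr.offset_idx - tr.onset_idx + 1 < 2:
            logger.warning("skipping too-short trial %s", tr.trial_id)
            continue
        valid.append(tr)
    if not valid:
        raise ParameterError("no valid trials to build a model input set from")
    pids = {tr.participant_id for tr in valid}
    targets = {tr.target for tr in valid}
    if len(pids) != 1 or len(targets) != 1:
        raise ParameterError(
            f"trials span multiple participants/targets: {pids} x {targets}"
        )
    fs = valid[0].fs
    if any(tr.fs != fs for tr in valid):
        raise ParameterError("trials have mixed sampling rates")

    durations = np.array([tr.duration_s for tr in valid])
    mean_dur = float(durations.mean())
    n_samples = max(2, int(round(mean_dur * fs)))

    times, angles = [], []
    for tr in valid:
        seg = tr.segment_angle()
        # trial time relative to its own onset, in units of the mean duration
        t = (np.arange(seg.size) / fs) / mean_dur
        bw = bandwidth_mult * (t[-1] - t[0]) / (t.size - 1)
        q = np.linspace(t[0], t[-1], n_samples)
        yhat = grnn_regress(t, seg, q, bw)
        times.append(q)
        angles.append(yhat)

    t_all = np.concatenate(times)
    a_all = np.concatenate(angles)
    sp_time = ScaleParams("time", float(t_all.min()), float(t_all.max()))
    sp_angle = ScaleParams("angle", float(a_all.min()), float(a_all.max()))
    points = np.column_stack([sp_time.scale(t_all), sp_angle.scale(a_all)])
    tr0 = valid[0]
    return ModelInputSet(
        participant_id=tr0.participant_id,
        target=tr0.target,
        n_samples=n_samples,
        points=points,
        scale_params={"time": sp_time, "angle": sp_angle},
        n_trials=len(valid),
        group=tr0.group,
    )
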