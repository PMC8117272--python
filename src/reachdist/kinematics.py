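"""Clinical kinematic measures of reaching and TSRT spasticity estimation.

Five standard reach-to-grasp measures are computed per trial and averaged
per participant and target: movement time, final elbow extension angle,
mean elbow velocity, peak elbow velocity, and the number of elbow velocity
peaks (a smoothness proxy). Final angle and mean velocity are aggregated
with circular means (values treated modulo 360); movement time, peak
velocity and peak count with arithmetic means.

The tonic stretch reflex threshold (TSRT) — the joint angle at which the
stretch reflex is recruited at zero stretch velocity — is extrapolated by
ordinary least-squares regression of dynamic threshold angles on stretch
velocity, evaluated at velocity zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ParameterError, Trial, differentiate

logger = logging.getLogger("reachdist")


class DegenerateMeanError(ValueError):
    """Circular mean is undefined (antipodal inputs, near-zero resultant)."""


@dataclass
class KinematicSummary:
    """Per participant-by-target averages of the five kinematic measures."""

    participant_id: str
    target: str
    movement_time: float  # s, arithmetic mean
    final_angle: float  # deg, circular mean
    mean_velocity: float  # deg/s, circular mean by default
    peak_velocity: float  # deg/s, arithmetic mean
    n_velocity_peaks: float  # mean count per trial
    n_trials: int
    group: str = ""


@dataclass
class DynamicThresholdSet:
    """(stretch velocity, dynamic threshold angle) pairs for one participant."""

    observations: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise ParameterError("need at least two dynamic threshold observations")
        v = np.array([o[0] for o in self.observations], dtype=float)
        if np.any(v <= 0):
            raise ParameterError("stretch velocities must be positive")
        if np.allclose(v, v[0]):
            raise ParameterError("stretch velocities must not all be equal")

    @property
    def velocities(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations], dtype=float)


@dataclass
class TSRTEstimate:
    """TSRT regression result: intercept at zero velocity, slope and R^2."""

    tsrt_angle: float  # deg
    slope: float  # deg per (deg/s)
    r_squared: float


def circular_mean(angles_deg: np.ndarray) -> float:
    """Mean direction of angles in degrees, wrapped to [0, 360).

    The mean of the unit vectors; raises if the resultant length is
    (numerically) zero, in which case the mean direction is undefined.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ParameterError("cannot average an empty angle set")
    z = np.exp(1j * a).mean()
    if abs(z) < 1e-9:
        raise DegenerateMeanError("near-zero resultant: circular mean undefined")
    mean = float(np.degrees(np.angle(z)) % 360.0)
    return 0.0 if mean >= 360.0 else mean


def movement_time(onset_idx: int, offset_idx: int, fs: float) -> float:
    """Segment duration in seconds: (offset - onset) / fs."""
    if not onset_idx < offset_idx:
        raise ParameterError(f"onset {onset_idx} must precede offset {offset_idx}")
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    return (offset_idx - onset_idx) / fs


def mean_velocity_thresholded(vel: np.ndarray) -> float:
    """Mean of velocity samples above 10% of the maximum.

    Restricting the mean to the above-threshold portion keeps segmented
    (stop-and-go) movements comparable to smooth ones.
    """
    v = np.asarray(vel, dtype=float)
    if v.size == 0 or np.max(v) <= 0:
        raise ParameterError("velocity trace has no positive samples")
    mask = v > 0.1 * np.max(v)
    return float(v[mask].mean())


def count_velocity_peaks(vel: np.ndarray, fs: float, hold: float = 0.1) -> int:
    """Number of velocity peaks: qualifying rising phases of the trace.

    The velocity is differentiated and maximal runs of strictly positive
    acceleration are counted when they last more than ``hold`` seconds
    (run length / fs > hold). Degenerate inputs yield 0.
    """
    v = np.asarray(vel, dtype=float)
    if v.size < 3:
        return 0
    acc = differentiate(v, fs)
    count = 0
    run = 0
    for a in np.append(acc > 0, False):
        if a:
            run += 1
        else:
            if run / fs > hold:
                count += 1
            run = 0
    return count


def trial_measures(trial: Trial, hold: float = 0.1) -> dict[str, float]:
    """The five kinematic measures for one segmented trial.

    Elbow velocity is the derivative of the angle series within
    [onset, offset]; peak and mean velocity are computed on its magnitude.
    """
    if not trial.segmented:
        raise ParameterError("trial must be segmented before measuring")
    seg = trial.segment_angle()
    vel = differentiate(seg, trial.fs)
    speed = np.abs(vel)
    return {
        "movement_time": movement_time(trial.onset_idx, trial.offset_idx, trial.fs),
        "final_angle": float(trial.angle[trial.offset_idx]),
        "mean_velocity": mean_velocity_thresholded(speed),
        "peak_velocity": float(speed.max()),
        "n_velocity_peaks": float(count_velocity_peaks(vel, trial.fs, hold=hold)),
    }


def summarize_participant_target(
    trials: list[Trial], hold: float = 0.1, circular_velocity: bool = True
) -> KinematicSummary:
    """Aggregate per-trial measures for one participant and target.

    Final angle and mean velocity are combined with circular means (their
    values treated modulo 360 deg); movement time, peak velocity and peak
    count with arithmetic means. ``circular_velocity=False`` switches the
    mean-velocity aggregate to an arithmetic mean, which avoids wrap-around
    for velocities above 360 deg/s (a warning is logged whenever wrapping
    would occur).
    """
    valid = [t for t in trials if not t.discarded and t.segmented]
    if not valid:
        raise ParameterError("no valid trials to summarize")
    pids = {t.participant_id for t in valid}
    targets = {t.target for t in valid}
    if len(pids) != 1 or len(targets) != 1:
        raise ParameterError(f"trials span multiple participants/targets: {pids} x {targets}")

    rows = [trial_measures(t, hold=hold) for t in valid]
    mean_vels = np.array([r["mean_velocity"] for r in rows])
    if circular_velocity:
        if np.any(mean_vels >= 360.0):
            logger.warning(
                "circular aggregation of mean velocities >= 360 deg/s wraps "
                "(max %.1f); consider circular_velocity=False", mean_vels.max()
            )
        mean_velocity = circular_mean(mean_vels)
    else:
        mean_velocity = float(mean_vels.mean())

    t0 = valid[0]
    return KinematicSummary(
        participant_id=t0.participant_id,
        target=t0.target,
        movement_time=float(np.mean([r["movement_time"] for r in rows])),
        final_angle=circular_mean([r["final_angle"] for r in rows]),
        mean_velocity=mean_velocity,
        peak_velocity=float(np.mean([r["peak_velocity"] for r in rows])),
        n_velocity_peaks=float(np.mean([r["n_velocity_peaks"] for r in rows])),
        n_trials=len(valid),
        group=t0.group,
    )


def estimate_tsrt(obs: DynamicThresholdSet) -> TSRTEstimate:
    """Extrapolate the TSRT by OLS of threshold angle on stretch velocity.

    The tonic threshold is the regression line's intercept (the dynamic
    threshold extrapolated to zero stretch velocity).
    """
    res = stats.linregress(obs.velocities, obs.angles)
    return TSRTEstimate(
        tsrt_angle=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
    )
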