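"""Signal conditioning and movement segmentation for reach-to-grasp trials.

Raw motion-capture landmark trajectories (shoulder, elbow and wrist joint
centers, sampled at a known rate, typically 120 Hz) are zero-phase low-pass
filtered, converted to an elbow angle (the 3-point included angle at the
elbow, in degrees; 180 deg = full extension) and a forearm tangential speed,
and cut to the first reach segment by a relative velocity-threshold rule:
the movement starts when the speed rises above 10% of its peak and holds
there for at least 0.1 s, and ends just before it falls below that threshold
and stays below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy import signal

logger = logging.getLogger("reachdist")

#: The four reach target locations: near-center, far-center, contralateral,
#: ipsilateral.
TARGETS = ("NC", "FC", "CL", "IL")

#: Effective forearm lever arm (cm) used to convert elbow angular velocity
#: (deg/s) into an equivalent wrist tangential speed (cm/s) when only an
#: angle series is available.
FOREARM_LEVER_CM = 25.0


class ParameterError(ValueError):
    """A configuration value is outside its valid range."""


class SegmentationError(ValueError):
    """A speed trace does not contain a detectable movement."""


class DegenerateGeometryError(ValueError):
    """Landmarks coincide, so a joint angle is undefined."""


@dataclass
class LandmarkSeries:
    """Raw 3-D joint-center trajectories for one recorded trial.

    Coordinates are in cm; all three landmark arrays have shape (n, 3) with
    equal n >= 2.
    """

    participant_id: str
    target: str
    trial_id: str
    fs: float
    shoulder: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray

    def __post_init__(self) -> None:
        self.shoulder = np.asarray(self.shoulder, dtype=float)
        self.elbow = np.asarray(self.elbow, dtype=float)
        self.wrist = np.asarray(self.wrist, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        shapes = {a.shape for a in (self.shoulder, self.elbow, self.wrist)}
        if len(shapes) != 1:
            raise ParameterError(f"landmark arrays differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or shape[1] != 3 or shape[0] < 2:
            raise ParameterError(f"landmark arrays must be (n>=2, 3), got {shape}")
        for name in ("shoulder", "elbow", "wrist"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite coordinates in {name}")

    def __len__(self) -> int:
        return self.shoulder.shape[0]


@dataclass
class Trial:
    """One reach movement: elbow angle and forearm speed series plus bounds.

    ``onset_idx``/``offset_idx`` are 0-based sample indices of the analyzed
    reach segment; they are ``None`` until the trial has been segmented.
    """

    participant_id: str
    target: str
    trial_id: str
    fs: float
    angle: np.ndarray  # elbow angle, deg
    speed: np.ndarray  # forearm tangential speed, cm/s
    onset_idx: Optional[int] = None
    offset_idx: Optional[int] = None
    group: str = ""
    discarded: bool = False
    discard_reason: str = ""
    offset_fallback: bool = False

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.angle.ndim != 1 or self.speed.ndim != 1:
            raise ParameterError("angle and speed must be 1-D series")
        if self.angle.shape != self.speed.shape:
            raise ParameterError("angle and speed must have equal length")
        if not np.all(np.isfinite(self.angle)):
            raise ParameterError("non-finite angle samples")
        if self.onset_idx is not None and self.offset_idx is not None:
            if not 0 <= self.onset_idx < self.offset_idx < len(self.angle):
                raise ParameterError(
                    f"invalid bounds {self.onset_idx}..{self.offset_idx} "
                    f"for length {len(self.angle)}"
                )

    def __len__(self) -> int:
        return len(self.angle)

    @property
    def segmented(self) -> bool:
        return self.onset_idx is not None and self.offset_idx is not None

    @property
    def duration_s(self) -> float:
        """Duration of the segmented reach in seconds."""
        if not self.segmented:
            raise ValueError("trial has not been segmented")
        return (self.offset_idx - self.onset_idx) / self.fs

    def segment_angle(self) -> np.ndarray:
        """Angle samples within [onset, offset] inclusive."""
        if not self.segmented:
            raise ValueError("trial has not been segmented")
        return self.angle[self.onset_idx : self.offset_idx + 1]


class MovementBounds(NamedTuple):
    onset: int
    offset: int
    offset_fallback: bool


def butterworth_zero_phase(
    series: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 3
) -> np.ndarray:
    """Forward-backward (zero phase lag) low-pass Butterworth filter.

    The two-pass application squares the magnitude response, so the
    effective attenuation at the cutoff is -6 dB rather than -3 dB. DC gain
    is exactly 1.
    """
    y = np.asarray(series, dtype=float)
    if cutoff <= 0 or fs <= 2 * cutoff:
        raise ParameterError(
            f"cutoff must lie in (0, fs/2); got cutoff={cutoff}, fs={fs}"
        )
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    if y.ndim != 1:
        raise ParameterError("series must be 1-D")
    if len(y) < 3 * order:
        raise SegmentationError(
            f"series of length {len(y)} too short to filter (need >= {3 * order})"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), len(y) - 1)
    return signal.filtfilt(b, a, y, padlen=padlen)


def differentiate(series: np.ndarray, fs: float) -> np.ndarray:
    """Differentiate a sampled signal.

    Central differences at interior samples, one-sided differences at the
    ends; exact for straight lines, second-order accurate in the interior.
    Output has the same length as the input, in input units per second.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ParameterError("need a 1-D series of length >= 2 to differentiate")
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    return np.gradient(y, 1.0 / fs)


def tangential_speed(positions: np.ndarray, fs: float) -> np.ndarray:
    """Euclidean norm of the componentwise derivative of a 3-D trajectory."""
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
        raise ParameterError(f"positions must be (n>=2, 3), got {p.shape}")
    vel = np.column_stack([differentiate(p[:, k], fs) for k in range(3)])
    return np.linalg.norm(vel, axis=1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as inclusive (start, end)."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    changes = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = np.r_[0, changes + 1]
    ends = np.r_[changes, m.size - 1]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if m[s]]


def detect_movement_bounds(
    speed: np.ndarray, fs: float, frac: float = 0.1, hold: float = 0.1
) -> MovementBounds:
    """Locate movement onset and offset by a relative speed threshold.

    Onset is the first sample of the first run where the speed exceeds
    ``frac`` of its peak and stays above for at least ``hold`` seconds.
    Offset is the last sample at or above threshold before the speed drops
    below threshold (after the global peak) and stays below for at least
    ``hold`` seconds; a below-threshold run that extends to the end of the
    recording qualifies regardless of its length. If the speed never
    re-crosses below the threshold, offset falls back to the last sample and
    ``offset_fallback`` is set (segmented motion that never comes to rest
    within the recording).
    """
    v = np.asarray(speed, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ParameterError("speed must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ParameterError("non-finite speed samples")
    if not 0 < frac < 1:
        raise ParameterError(f"frac must lie in (0, 1), got {frac}")
    peak = float(v.max())
    if peak <= 0:
        raise SegmentationError("no movement: speed is never positive")
    hold_n = int(round(hold * fs))
    if hold_n < 1:
        raise ParameterError(f"hold of {hold} s is under one sample at fs={fs}")
    thr = frac * peak

    onset = None
    for s, e in _runs(v > thr):
        if e - s + 1 >= hold_n:
            onset = s
            break
    if onset is None:
        raise SegmentationError(
            f"no onset: speed never holds above {frac:.0%} of peak for {hold} s"
        )

    peak_idx = int(np.argmax(v))
    offset = None
    fallback = False
    for s, e in _runs(v < thr):
        if s <= peak_idx or s - 1 <= onset:
            continue
        if e - s + 1 >= hold_n or e == v.size - 1:
            offset = s - 1
            break
    if offset is None:
        offset = v.size - 1
        fallback = True
        logger.debug("offset fallback: tail never holds below threshold")
    return MovementBounds(onset, offset, fallback)


def elbow_angle_series(
    shoulder: np.ndarray, elbow: np.ndarray, wrist: np.ndarray
) -> np.ndarray:
    """Per-sample included angle at the elbow, in degrees.

    The angle between the vectors elbow->shoulder and elbow->wrist; 180 deg
    is full extension. Invariant to rigid rotation and translation of all
    three landmarks.
    """
    s = np.atleast_2d(np.asarray(shoulder, dtype=float))
    e = np.atleast_2d(np.asarray(elbow, dtype=float))
    w = np.atleast_2d(np.asarray(wrist, dtype=float))
    if not s.shape == e.shape == w.shape:
        raise ParameterError("landmark arrays must have equal shapes")
    u = s - e
    v = w - e
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise DegenerateGeometryError("elbow coincides with shoulder or wrist")
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def trial_from_landmarks(
    series: LandmarkSeries, cutoff: float = 6.0, order: int = 3
) -> Trial:
    """Filter landmark coordinates and derive the elbow angle / forearm speed.

    Each coordinate channel is zero-phase filtered before angles and speeds
    are computed; the forearm tangential speed is taken at the wrist joint
    center.
    """
    def _filt(p: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [butterworth_zero_phase(p[:, k], series.fs, cutoff, order) for k in range(3)]
        )

    sh, el, wr = _filt(series.shoulder), _filt(series.elbow), _filt(series.wrist)
    angle = elbow_angle_series(sh, el, wr)
    speed = tangential_speed(wr, series.fs)
    return Trial(
        participant_id=series.participant_id,
        target=series.target,
        trial_id=series.trial_id,
        fs=series.fs,
        angle=angle,
        speed=speed,
    )


def segment_trial(
    trial: Trial,
    cutoff: float = 6.0,
    order: int = 3,
    frac: float = 0.1,
    hold: float = 0.1,
) -> Trial:
    """Return a copy of the trial with filtered traces and movement bounds."""
    if trial.discarded:
        raise SegmentationError(
            f"trial {trial.trial_id} was discarded: {trial.discard_reason}"
        )
    angle = butterworth_zero_phase(trial.angle, trial.fs, cutoff, order)
    speed = butterworth_zero_phase(trial.speed, trial.fs, cutoff, order)
    bounds = detect_movement_bounds(speed, trial.fs, frac=frac, hold=hold)
    return replace(
        trial,
        angle=angle,
        speed=speed,
        onset_idx=bounds.onset,
        offset_idx=bounds.offset,
        offset_fallback=bounds.offset_fallback,
    )
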