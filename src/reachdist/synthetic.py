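"""Synthetic reach-trial and cohort generation.

No clinical recordings ship with this package, so every pipeline stage is
exercised on simulated elbow trajectories. A trial is a superposition of
minimum-jerk submovements (position profile 10*tau^3 - 15*tau^4 + 6*tau^5,
single-peaked bell velocity) from a start angle to a target-dependent end
angle, plus Gaussian measurement noise, with rest padding on both sides so
threshold segmentation sees a quiet baseline. Healthy-like movements are
fast, smooth (one submovement) and low-noise; stroke-like movements are
slow, segmented into several overlapping submovements, noisier, and show a
reduced-extension endpoint.

Cohort generation adds participant-level random effects (offsets on
duration and endpoint) on top of trial-to-trial variability, mirroring the
participant random-effect structure used when such data are analyzed with
linear mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import FOREARM_LEVER_CM, ParameterError, Trial, differentiate

#: Included elbow angle at each target's endpoint (deg); farther targets
#: require more elbow extension.
TARGET_END_ANGLES = {"NC": 130.0, "FC": 150.0, "CL": 148.0, "IL": 146.0}


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on [0, 1], clamped outside."""
    t = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return t**3 * (10.0 - 15.0 * t + 6.0 * t * t)


@dataclass
class TrialParams:
    """Generative parameters of one simulated reach."""

    duration: float  # s, onset to offset of the full movement
    start_angle: float  # deg
    end_angle: float  # deg
    n_submovements: int = 1
    submovement_spacing: float = 0.0  # s between successive submovement onsets
    noise_sd: float = 0.0  # deg, white measurement noise on the angle
    fs: float = 120.0
    pad: float = 0.35  # s of rest before and after the movement
    amplitudes: np.ndarray | None = None  # fractional, sums to 1

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0 or self.pad < 0 or self.noise_sd < 0:
            raise ParameterError("duration/fs must be positive, pad/noise nonnegative")
        if self.n_submovements < 1 or self.submovement_spacing < 0:
            raise ParameterError("need n_submovements >= 1 and spacing >= 0")
        if self.duration <= (self.n_submovements - 1) * self.submovement_spacing:
            raise ParameterError(
                f"duration {self.duration}s cannot hold {self.n_submovements} "
                f"submovements spaced {self.submovement_spacing}s apart"
            )
        if self.amplitudes is not None:
            a = np.asarray(self.amplitudes, dtype=float)
            if a.size != self.n_submovements or not np.isclose(a.sum(), 1.0):
                raise ParameterError("amplitudes must match n_submovements and sum to 1")
            self.amplitudes = a


def simulate_trial(
    p: TrialParams,
    seed: int,
    participant_id: str = "P00",
    target: str = "NC",
    trial_id: str = "T00",
    group: str = "",
) -> Trial:
    """Simulate one reach trial; the same seed reproduces the trial exactly.

    The angle trace is start + (end - start) * sum of minimum-jerk
    submovement profiles (amplitudes summing to 1, equal unless given) plus
    Gaussian noise. The forearm tangential speed trace is the magnitude of
    the noise-free angular velocity scaled by the forearm lever arm, so
    speed and angle describe the same movement.
    """
    rng = np.random.default_rng(seed)
    n_pad = int(round(p.pad * p.fs))
    n = n_pad + int(round(p.duration * p.fs)) + n_pad + 1
    t = np.arange(n) / p.fs
    d_sub = p.duration - (p.n_submovements - 1) * p.submovement_spacing
    amps = (
        p.amplitudes
        if p.amplitudes is not None
        else np.full(p.n_submovements, 1.0 / p.n_submovements)
    )
    pos = np.zeros(n)
    for j in range(p.n_submovements):
        onset = p.pad + j * p.submovement_spacing
        pos += amps[j] * minimum_jerk((t - onset) / d_sub)
    angle_clean = p.start_angle + (p.end_angle - p.start_angle) * pos
    speed = np.abs(differentiate(angle_clean, p.fs)) * (FOREARM_LEVER_CM * np.pi / 180.0)
    angle = angle_clean + rng.normal(0.0, p.noise_sd, n) if p.noise_sd > 0 else angle_clean
    return Trial(
        participant_id=participant_id,
        target=target,
        trial_id=trial_id,
        fs=p.fs,
        angle=angle,
        speed=speed,
        group=group,
    )


@dataclass
class GroupParams:
    """Distributions of trial parameters for one cohort group."""

    duration_mean: float  # s
    duration_sd: float  # s, trial-to-trial
    duration_participant_sd: float  # s, between participants
    n_submovements_min: int
    n_submovements_max: int
    submovement_spacing: float  # s
    noise_sd: float  # deg
    endpoint_shift: float  # deg subtracted from the target end angle
    endpoint_sd: float  # deg, trial-to-trial
    endpoint_participant_sd: float  # deg, between participants
    start_angle: float = 60.0  # deg, flexed initial posture


#: Healthy-like defaults: fast (~0.67 s), smooth single-submovement reaches
#: with low noise and full extension to the target.
CONTROL_PARAMS = GroupParams(
    duration_mean=0.67, duration_sd=0.07, duration_participant_sd=0.04,
    n_submovements_min=1, n_submovements_max=1, submovement_spacing=0.0,
    noise_sd=0.25, endpoint_shift=0.0, endpoint_sd=1.5,
    endpoint_participant_sd=2.0,
)

#: Stroke-like defaults: slow (~1.7 s), segmented (5-9 overlapping
#: submovements), variable reaches with a reduced-extension endpoint.
STROKE_PARAMS = GroupParams(
    duration_mean=1.70, duration_sd=0.20, duration_participant_sd=0.15,
    n_submovements_min=5, n_submovements_max=9, submovement_spacing=0.18,
    noise_sd=1.0, endpoint_shift=12.0, endpoint_sd=3.0,
    endpoint_participant_sd=4.0,
)


@dataclass
class CohortConfig:
    """Cohort composition and group-level generative parameters."""

    n_controls: int = 13
    n_stroke: int = 13
    trials_per_target: int = 10
    targets: tuple[str, ...] = ("NC", "FC", "CL", "IL")
    control: GroupParams = field(default_factory=lambda: replace(CONTROL_PARAMS))
    stroke: GroupParams = field(default_factory=lambda: replace(STROKE_PARAMS))
    fs: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_stroke < 1 or self.trials_per_target < 1:
            raise ParameterError("group sizes and trials per target must be >= 1")
        if not self.stroke.duration_mean > self.control.duration_mean:
            raise ParameterError("stroke mean duration must exceed control's")
        if self.stroke.n_submovements_min < self.control.n_submovements_min:
            raise ParameterError("stroke submovement count must be >= control's")
        unknown = set(self.targets) - set(TARGET_END_ANGLES)
        if unknown:
            raise ParameterError(f"unknown targets {unknown}")


def _draw_trial_params(
    rng: np.random.Generator,
    gp: GroupParams,
    target: str,
    fs: float,
    duration_offset: float,
    endpoint_offset: float,
) -> TrialParams:
    nsub = int(rng.integers(gp.n_submovements_min, gp.n_submovements_max + 1))
    duration = gp.duration_mean + duration_offset + rng.normal(0.0, gp.duration_sd)
    # keep the submovement train feasible within the drawn duration
    duration = max(duration, (nsub - 1) * gp.submovement_spacing + 0.2)
    end = (
        TARGET_END_ANGLES[target]
        - gp.endpoint_shift
        + endpoint_offset
        + rng.normal(0.0, gp.endpoint_sd)
    )
    end = float(np.clip(end, gp.start_angle + 20.0, 179.0))
    if nsub > 1:
        amps = rng.dirichlet(np.full(nsub, 4.0))
    else:
        amps = None
    return TrialParams(
        duration=duration,
        start_angle=gp.start_angle,
        end_angle=end,
        n_submovements=nsub,
        submovement_spacing=gp.submovement_spacing,
        noise_sd=gp.noise_sd,
        fs=fs,
        amplitudes=amps,
    )


def simulate_cohort(cfg: CohortConfig) -> list[Trial]:
    """Generate the full labeled cohort; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    trials: list[Trial] = []
    groups = (
        ("control", "C", cfg.n_controls, cfg.control),
        ("stroke", "S", cfg.n_stroke, cfg.stroke),
    )
    for group, prefix, n_participants, gp in groups:
        for ip in range(n_participants):
            pid = f"{prefix}{ip + 1:02d}"
            dur_off = rng.normal(0.0, gp.duration_participant_sd)
            end_off = rng.normal(0.0, gp.endpoint_participant_sd)
            for target in cfg.targets:
                for it in range(cfg.trials_per_target):
                    params = _draw_trial_params(rng, gp, target, cfg.fs, dur_off, end_off)
                    trial_seed = int(rng.integers(2**31))
                    trials.append(
                        simulate_trial(
                            params,
                            trial_seed,
                            participant_id=pid,
                            target=target,
                            trial_id=f"T{it + 1:02d}",
                            group=group,
                        )
                    )
    return trials


def simulate_threshold_data(
    tsrt_angle: float,
    slope: float,
    velocities: np.ndarray,
    noise_sd: float,
    seed: int,
) -> "DynamicThresholdSet":
    """Dynamic stretch-threshold pairs from a known line plus angle noise.

    threshold_angle = tsrt_angle + slope * velocity + N(0, noise_sd); used
    for TSRT recovery checks and as example input for TSRT estimation.
    """
    from .kinematics import DynamicThresholdSet

    rng = np.random.default_rng(seed)
    v = np.asarray(velocities, dtype=float)
    a = tsrt_angle + slope * v + rng.normal(0.0, noise_sd, v.size)
    return DynamicThresholdSet(observations=list(zip(v.tolist(), a.tolist())))
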