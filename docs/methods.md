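# Methods

This note documents the models, numerical choices and known limitations of
`reachdist`, in the order the pipeline runs.

## Preprocessing and segmentation

Sensor-derived coordinate channels are filtered with a two-way (zero phase
lag) low-pass 3rd-order Butterworth filter, 6 Hz cutoff by default; the
forward–backward application squares the magnitude response, so the
effective attenuation at cutoff is −6 dB. Differentiation uses central
differences with one-sided ends (second-order accurate in the interior,
no phase lag).

The elbow angle is the 3-point included angle at the elbow joint center
between the elbow→shoulder and elbow→wrist vectors, in degrees, with 180°
= full extension. For pure flexion/extension this equals the Cardan
flexion component up to sign and a constant offset; reported final-angle
values are therefore convention-dependent, and comparisons across studies
must account for the offset. Full Cardan decomposition from sensor
orientation frames is out of scope.

Movement bounds come from a relative speed threshold: onset is the first
sample where the forearm tangential speed exceeds 10% of its peak and
holds above threshold for at least 0.1 s; offset is the last sample at or
above threshold before the speed falls below it (after the global peak)
and stays below for at least 0.1 s. A below-threshold run that reaches the
end of the recording qualifies regardless of its length, because the
recording cannot contradict it; when the speed never re-crosses the
threshold at all, the offset falls back to the last sample and the trial
is flagged (segmented motion that never comes to rest). The threshold is
relative, so bounds are invariant to positive rescaling of the speed
trace. Trial discard for recording errors or task failures is an input
flag, not an algorithm.

## Spatiotemporal normalization

Time and angle have incommensurate units and ranges; modeling them jointly
without rescaling would weight the larger-valued dimension arbitrarily.
Per participant and target: each trial's time axis is first expressed in
units of the set's mean movement duration; each trial's angle-versus-time
function is approximated by Gaussian-kernel regression (a general
regression neural network, i.e. Nadaraya–Watson with a Gaussian kernel)
and resampled at n = round(mean duration × fs) uniformly spaced points
over the trial's own segment, so duration differences between trials
survive; both dimensions are then min–max scaled to [−1, 1] with extrema
pooled across the set's trials.

Choices made where the design was open:

* **Pooled (not per-trial) min–max.** Per-trial scaling would erase the
  relative amplitude differences between trials that the mixture model is
  supposed to capture.
* **Kernel bandwidth** = 2 × the mean spacing of the trial's time samples
  (configurable). This tracks sampling density: wide enough to average
  measurement noise, narrow enough that the regression follows the
  trajectory. The estimate is a convex combination of training values, so
  it cannot overshoot the observed angle range; it does carry a
  bandwidth-dependent smoothing bias of order a degree near segment
  boundaries on strongly curved inputs.
* **Per-trial query grids** (not a common grid), preserving each trial's
  own support in the scaled frame.

## Mixture modeling and order selection

Each pooled point set is fitted with full-covariance Gaussian mixtures by
EM (delegated to scikit-learn), initialized from the best of 10 k-means++
runs at a fixed seed; initial weights are cluster fractions, means are
centroids, covariances are within-cluster sample covariances. Covariances
carry a 1e−6 diagonal regularization so duplicated resampled points cannot
collapse a component; components whose weight vanishes numerically are
dropped and the rest renormalized. One EM run per candidate order, seed
recorded in the model, which makes every fit reproducible.

Order selection minimizes BIC = k ln(n) − 2 ln L over K = 2…25, with
k = (K−1) + Kd + Kd(d+1)/2 = 6K − 1 free parameters for d = 2; ties break
toward the smaller order.

Numerical settings: `em_fit` defaults to a 1e−6 convergence tolerance on
the per-sample log-likelihood change and 500 iterations. The pipeline
(`RunConfig`) uses 1e−3 / 150 iterations and stops the order sweep once
BIC has not improved for 4 consecutive orders. Rationale: GRNN-resampled
trajectories are dense and smooth, so past the knee of the BIC curve the
criterion declines only marginally for many orders while EM iteration
counts grow; the looser pipeline settings select the knee, cut the full
26-participant cohort run from over half an hour to under three minutes,
and leave the group-level contrasts unchanged. Both sets of values are
configurable.

## Distances

**Component KL** is the 2-D Gaussian closed form
KL(a‖b) = ½[tr(Σ_b⁻¹Σ_a) + Δμᵀ Σ_b⁻¹ Δμ − d + ln(det Σ_b/det Σ_a)].

**Variational KLD** between mixtures follows the variational bound of
Hershey and Olsen, computed in log-space (logsumexp) to avoid underflow.
It is exact for single-component mixtures, exactly zero for identical
mixtures (the sums cancel term by term), and accurate when each mixture's
components are internally well separated; its error grows with
inter-component overlap. The approximation is not guaranteed nonnegative,
so estimates are clamped below at 0. **BKLD** is the Jeffreys-style sum of
the two directions (symmetric by construction); **log-BKLD** is
ln(max(BKLD, 1e−12)), the floor keeping identical models finite.

**Hellinger distance** uses the identity ∫√(fg) = E_f[√(g/f)]: the
expectation is evaluated on the 2d+1 sigma points of each component of f
(spread √(d+κ) times the Cholesky columns of the covariance; center weight
κ/(d+κ)), with the density ratio formed in log-space. κ = 1 for d = 2, the
classical choice d + κ = 3 that matches fourth-moment terms for Gaussians.
The coefficient is estimated expanding under f and under g and the two
averaged, making the returned distance exactly symmetric; BC is clamped to
[0, 1] and complements below 1e−12 snap to zero so that HD(f, f) = 0
exactly rather than √(machine-ε). The unscented quadrature is a 5-point
rule per component: deterministic and fast, exact neither for Gaussian
pairs (relative BC error ~10⁻⁴ at moderate overlap) nor in the
near-disjoint regime, where the sigma points cannot see the overlap mass.
A closed-form single-Gaussian Hellinger (`gaussian_hellinger`) is exposed
and serves as the oracle for the estimator in tests; Monte-Carlo
integration is kept as a test oracle only.

Nearest-neighbor scoring takes the minimum over the reference set, first
index on ties; references sharing the subject's participant id are always
excluded, which implements the leave-one-out baseline and guards against a
trivial zero when a subject appears in its own reference pool. All
distances are computed within-target.

## Kinematic measures

Per trial, within [onset, offset]: movement time = (offset − onset)/fs;
final angle = the angle at the offset sample (the natural endpoint of the
analyzed segment; the instant is otherwise arbitrary); elbow velocity =
derivative of the angle series, with peak velocity the maximum of its
magnitude; mean velocity the mean of magnitudes above 10% of the maximum
(keeping stop-and-go movements comparable); the peak count = number of
maximal runs of strictly positive acceleration lasting more than 0.1 s
(run length/fs > hold, so a rise must *stay* positive).

Aggregation per participant and target: circular means for final angle and
mean velocity (values taken modulo 360), arithmetic means for movement
time, peak velocity and peak count. Circular averaging of velocities wraps
for values above 360 deg/s; a warning is logged when that occurs and
`circular_velocity=False` switches to the arithmetic mean. The circular
mean raises when the resultant is numerically zero (antipodal inputs).

**TSRT** is the intercept of the ordinary least-squares regression of
dynamic threshold angles on stretch velocity — the spatial threshold
extrapolated to zero velocity — reported with the slope and R². At
physiological noise levels (SD ≈ 2° on 8 velocities) a single estimate
carries a standard error of about 1.5°; OLS is unbiased, so averages over
repeated measurements converge on the true threshold.

## Synthetic cohort

The generator emulates the reach-to-grasp protocol: four targets (NC, FC,
CL, IL), 10 trials per target, 120 Hz sampling. A trial is a superposition
of minimum-jerk submovements (position 10τ³ − 15τ⁴ + 6τ⁵, single-peaked
bell velocity; amplitudes sum to 1) from a flexed start (60° included
angle) to a target-dependent endpoint (130–150°), plus white angle noise
and 0.35 s rest padding. The forearm speed trace is the noise-free angular
speed scaled by a 25 cm lever arm, so speed and angle describe the same
movement.

Group defaults: control-like — 0.67 s mean duration, one submovement,
0.25° noise; stroke-like — 1.7 s mean duration, 5–9 submovements spaced
0.18 s (overlapping, hence segmented multi-peaked velocity), 1° noise, and
a 12° reduced-extension endpoint shift applied across targets. Participant
random effects are Gaussian offsets on duration and endpoint, mirroring
the participant random-effect structure of mixed-model analyses of such
data. Durations are clipped so a drawn submovement train always fits.

What the generator does **not** emulate: trunk compensation and
multi-joint coordination, signal-dependent noise, sensor drift and
occlusion artifacts, target-specific inter-joint differences beyond the
endpoint angle, and fatigue across trials. Passing pipeline tests on this
cohort therefore demonstrate that the machinery recovers the group
structure that was put in (direction and separation of group contrasts),
not that clinical effect sizes are reproduced.

## Problem sizes in tests and the acceptance script

The test suite validates the distance computations against closed forms
and against 10⁶-sample Monte-Carlo integration on 20 mixture pairs; order
selection on 20 simulated 3-component datasets of 3,000 points; TSRT
recovery over 100 seeds; and the full pipeline on the default 13+13
cohort. The byte-identical determinism check reruns a reduced cohort (4+4
participants, 2 targets), determinism being independent of problem size.
`scripts/acceptance.py` runs the full default cohort once; about three
minutes on one CPU.

## Known limitations

* The included-angle convention differs from sensor-frame Cardan angles by
  an offset; absolute final-angle values are not comparable across
  conventions.
* The variational KLD and unscented Hellinger are approximations with
  complementary failure modes (inter-component overlap, near-disjoint
  supports); both are well within a few percent of Monte-Carlo in the
  moderate-separation regime where movement models live, but BKLD values
  between nearly identical models and HD values near 1 should be read
  qualitatively.
* BIC order selection on densely resampled trajectories has a shallow
  optimum; the selected K depends mildly on EM tolerance, which is why the
  pipeline's numerical settings are recorded in the provenance output.
* Mixed-model statistics on the exported tables (group, target and
  spasticity effects) are intentionally left to external statistical
  tools; the package exports tidy CSVs for that purpose.
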