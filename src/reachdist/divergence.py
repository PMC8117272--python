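"""Stochastic distances between Gaussian mixture models of reach motion.

Two distances quantify how far a subject's movement model lies from
reference (healthy) models of the same target:

* the bidirectional Kullback-Leibler divergence (BKLD), the sum of the two
  directed KL divergences, each approximated by the variational bound of
  Hershey & Olsen built from closed-form component-pair Gaussian KLs — BKLD
  is unbounded above and sensitive to information loss when a dispersed
  model is approximated by a condensed one;
* Hellinger's distance (HD), sqrt(1 - Bhattacharyya coefficient), bounded
  on [0, 1], here estimated by integrating sqrt(g/f) with the unscented
  transform's sigma points of each mixture component — HD measures the
  separability of the two densities and is less affected by sheer motion
  variability.

A subject's final score against a reference cohort is the minimum over all
references (nearest-neighbor scoring), with the subject excluded from the
reference set by id for within-cohort (leave-one-out) baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .gmm import GaussianComponent, MixtureModel
from .preprocess import ParameterError

logger = logging.getLogger("reachdist")

#: Floor applied inside the log transform of BKLD, so identical models map
#: to ln(eps) instead of -inf.
LOG_BKLD_EPS = 1e-12

#: Distance metrics understood by nearest_neighbor_distance.
METRICS = ("BKLD", "logBKLD", "HD")


@dataclass
class DistanceResult:
    """Nearest-neighbor distance of a subject model to a reference cohort."""

    metric: str
    value: float
    subject_model_id: str
    nearest_ref_id: str
    all_ref_values: list[tuple[str, float]]
    target: str

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ParameterError(f"unknown metric {self.metric!r}")


def gaussian_kld(a: GaussianComponent, b: GaussianComponent) -> float:
    """Closed-form KL(a || b) between two Gaussians, >= 0 and 0 iff a == b.

    KL = 0.5 * [tr(Sb^-1 Sa) + (mb-ma)' Sb^-1 (mb-ma) - d + ln(det Sb / det Sa)]
    """
    if a.dim != b.dim:
        raise ParameterError("components have different dimensions")
    d = a.dim
    sa, sb = a.covariance, b.covariance
    sign_b, logdet_b = np.linalg.slogdet(sb)
    sign_a, logdet_a = np.linalg.slogdet(sa)
    if sign_a <= 0 or sign_b <= 0:
        raise ParameterError("singular covariance in KL computation")
    sb_inv = np.linalg.inv(sb)
    dm = b.mean - a.mean
    kl = 0.5 * (
        np.trace(sb_inv @ sa) + dm @ sb_inv @ dm - d + logdet_b - logdet_a
    )
    return float(max(kl, 0.0))


def gaussian_hellinger(a: GaussianComponent, b: GaussianComponent) -> float:
    """Closed-form Hellinger distance between two Gaussians, in [0, 1].

    BC = det(Sa)^{1/4} det(Sb)^{1/4} / det((Sa+Sb)/2)^{1/2}
         * exp(-(1/8) (ma-mb)' ((Sa+Sb)/2)^{-1} (ma-mb));  HD = sqrt(1 - BC).

    Exact; used as the oracle for the unscented estimator on single-Gaussian
    pairs.
    """
    if a.dim != b.dim:
        raise ParameterError("components have different dimensions")
    sa, sb = a.covariance, b.covariance
    sbar = 0.5 * (sa + sb)
    _, logdet_a = np.linalg.slogdet(sa)
    _, logdet_b = np.linalg.slogdet(sb)
    sign, logdet_bar = np.linalg.slogdet(sbar)
    if sign <= 0:
        raise ParameterError("singular covariance in Hellinger computation")
    dm = a.mean - b.mean
    log_bc = (
        0.25 * logdet_a + 0.25 * logdet_b - 0.5 * logdet_bar
        - 0.125 * dm @ np.linalg.inv(sbar) @ dm
    )
    bc = float(np.clip(np.exp(log_bc), 0.0, 1.0))
    return float(np.sqrt(1.0 - bc))


def variational_kld(f: MixtureModel, g: MixtureModel) -> float:
    """Variational approximation to KL(f || g) for Gaussian mixtures.

    D_var(f||g) = sum_a w_a * ln[ sum_a' w_a' e^{-KL(f_a||f_a')}
                                  / sum_b  p_b  e^{-KL(f_a||g_b)} ],
    with component-pair KLs in closed form and both sums taken in log-space.
    Exact for single-component mixtures and zero when f and g share their
    component list (the sums cancel term by term). The approximation is not
    guaranteed nonnegative, so the result is clamped below at 0.
    """
    if f.K == 0 or g.K == 0:
        raise ParameterError("empty mixture")
    log_wf = np.log(f.weights)
    log_wg = np.log(g.weights)
    kl_ff = np.array(
        [[gaussian_kld(fa, fa2) for fa2 in f.components] for fa in f.components]
    )
    kl_fg = np.array(
        [[gaussian_kld(fa, gb) for gb in g.components] for fa in f.components]
    )
    num = logsumexp(log_wf[None, :] - kl_ff, axis=1)
    den = logsumexp(log_wg[None, :] - kl_fg, axis=1)
    d = float(np.dot(f.weights, num - den))
    return max(d, 0.0)


def bkld(f: MixtureModel, g: MixtureModel) -> float:
    """Bidirectional KLD: D_var(f||g) + D_var(g||f). Symmetric and >= 0."""
    return variational_kld(f, g) + variational_kld(g, f)


def log_bkld(f: MixtureModel, g: MixtureModel) -> float:
    """Natural log of BKLD, floored at ln(1e-12) for identical models."""
    value = bkld(f, g)
    if value < LOG_BKLD_EPS:
        logger.debug("degenerate BKLD %.3g floored before log transform", value)
    return float(np.log(max(value, LOG_BKLD_EPS)))


def sigma_points(
    c: GaussianComponent, kappa: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unscented-transform sigma points and weights of one Gaussian.

    2d+1 points: the mean (weight kappa/(d+kappa)) and mean +/- the columns
    of the Cholesky factor of (d+kappa)*Sigma (weights 1/(2(d+kappa))). The
    weighted mean and scatter of the points reproduce the component's mean
    and covariance exactly.
    """
    d = c.dim
    if d + kappa <= 0:
        raise ParameterError(f"require d + kappa > 0, got d={d}, kappa={kappa}")
    scale = d + kappa
    L = np.linalg.cholesky(scale * c.covariance)
    pts = np.empty((2 * d + 1, d))
    pts[0] = c.mean
    pts[1 : d + 1] = c.mean + L.T  # row i is column i of L
    pts[d + 1 :] = c.mean - L.T
    w = np.full(2 * d + 1, 1.0 / (2.0 * scale))
    w[0] = kappa / scale
    return pts, w


def _bc_one_sided(f: MixtureModel, g: MixtureModel, kappa: float) -> float:
    """Unscented estimate of the Bhattacharyya coefficient, expanded under f.

    Writes int sqrt(f g) = E_f[sqrt(g/f)] and evaluates the expectation
    component-wise on sigma points; the density ratio is formed in
    log-space. Non-finite sigma-point evaluations are skipped with a
    warning.
    """
    bc = 0.0
    for comp in f.components:
        pts, w = sigma_points(comp, kappa)
        log_ratio = 0.5 * (g.logpdf(pts) - f.logpdf(pts))
        ok = np.isfinite(log_ratio)
        if not ok.all():
            logger.warning(
                "skipping %d degenerate sigma points in Hellinger estimate",
                int((~ok).sum()),
            )
        bc += comp.weight * float(np.dot(w[ok], np.exp(log_ratio[ok])))
    return float(np.clip(bc, 0.0, 1.0))


def hellinger_unscented(
    f: MixtureModel, g: MixtureModel, kappa: float = 1.0
) -> float:
    """Hellinger distance between mixtures via the unscented transform.

    The Bhattacharyya coefficient is estimated twice — expanding under f and
    under g — and the two estimates averaged, which makes the returned
    distance symmetric by construction. HD = sqrt(1 - BC), clamped to [0, 1].
    """
    bc = 0.5 * (_bc_one_sided(f, g, kappa) + _bc_one_sided(g, f, kappa))
    gap = np.clip(1.0 - bc, 0.0, 1.0)
    if gap < 1e-12:  # summation noise near BC = 1 would be amplified by sqrt
        return 0.0
    return float(np.sqrt(gap))


def nearest_neighbor_distance(
    subject: MixtureModel,
    refs: list[MixtureModel],
    metric: str,
    kappa: float = 1.0,
    exclude_self: bool = True,
) -> DistanceResult:
    """Minimal distance from a subject model to a reference cohort.

    Evaluates the metric against every reference for the subject's target
    and returns the minimum (first index wins on ties). With
    ``exclude_self`` (the default) references sharing the subject's
    participant id are removed first, which implements the leave-one-out
    baseline for within-cohort comparisons.
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; expected one of {METRICS}")
    pool = list(refs)
    if exclude_self:
        pool = [r for r in pool if r.participant_id != subject.participant_id]
    if not pool:
        raise ParameterError("empty reference set")
    for r in pool:
        if r.target != subject.target:
            raise ParameterError(
                f"reference {r.participant_id} has target {r.target!r}, "
                f"subject has {subject.target!r}"
            )
    if metric == "HD":
        values = [hellinger_unscented(subject, r, kappa) for r in pool]
    elif metric == "BKLD":
        values = [bkld(subject, r) for r in pool]
    else:
        values = [log_bkld(subject, r) for r in pool]
    best = int(np.argmin(values))
    return DistanceResult(
        metric=metric,
        value=float(values[best]),
        subject_model_id=subject.participant_id,
        nearest_ref_id=pool[best].participant_id,
        all_ref_values=[(r.participant_id, float(v)) for r, v in zip(pool, values)],
        target=subject.target,
    )
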