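"""Spatiotemporal Gaussian mixture modeling of pooled reach trajectories.

Each participant-by-target point cloud in the scaled (time, angle) plane is
modeled by a full-covariance Gaussian mixture fitted with EM (K-means
initialized); the number of components is chosen by the Bayesian
information criterion over a range of candidate orders (2-25 by default).

EM and K-means are delegated to scikit-learn; this module owns the
initialization policy, the BIC bookkeeping, order selection and the model
container used by the divergence measures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .preprocess import ParameterError

logger = logging.getLogger("reachdist")


@dataclass
class GaussianComponent:
    """One weighted 2-D Gaussian over the scaled (time, angle) plane."""

    weight: float
    mean: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2), symmetric positive-definite

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.mean.size
        if self.covariance.shape != (d, d):
            raise ParameterError(
                f"covariance shape {self.covariance.shape} does not match dim {d}"
            )
        if not 0 < self.weight <= 1 + 1e-9:
            raise ParameterError(f"weight must lie in (0, 1], got {self.weight}")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() <= 0:
            raise ParameterError(f"covariance not positive-definite (eigs {eig})")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class MixtureModel:
    """A fitted Gaussian mixture with its diagnostics."""

    components: list[GaussianComponent]
    log_likelihood: float
    n_points: int
    seed: int = 0
    participant_id: str = ""
    target: str = ""
    group: str = ""
    bic: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.components:
            raise ParameterError("mixture must have at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"component weights sum to {total}, expected 1")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        """Log mixture density at each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logs = np.empty((self.K, X.shape[0]))
        for i, c in enumerate(self.components):
            logs[i] = np.log(c.weight) + multivariate_normal.logpdf(
                X, mean=c.mean, cov=c.covariance
            )
        return logsumexp(logs, axis=0)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "logL": self.log_likelihood,
            "bic": self.bic,
            "n_points": self.n_points,
            "seed": self.seed,
            "participant": self.participant_id,
            "target": self.target,
            "group": self.group,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        comps = [
            GaussianComponent(w, np.array(m), np.array(c))
            for w, m, c in zip(d["weights"], d["means"], d["covariances"])
        ]
        return cls(
            components=comps,
            log_likelihood=d["logL"],
            n_points=d["n_points"],
            seed=d.get("seed", 0),
            participant_id=d.get("participant", ""),
            target=d.get("target", ""),
            group=d.get("group", ""),
            bic=d.get("bic", float("nan")),
            converged=d.get("converged", True),
        )


def kmeans_init(
    points: np.ndarray, K: int, seed: int, reg: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means initialization for EM: weights, means and covariances.

    Runs k-means++ with 10 restarts at a fixed seed and keeps the best
    inertia; initial weights are cluster fractions, means are centroids, and
    covariances are within-cluster sample covariances with ``reg`` added to
    the diagonal so singleton or collinear clusters stay positive-definite.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if n < K:
        raise ParameterError(f"{n} points cannot seed {K} clusters")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    weights = np.empty(K)
    means = km.cluster_centers_.copy()
    covs = np.empty((K, d, d))
    for k in range(K):
        members = X[labels == k]
        weights[k] = max(len(members), 1) / n
        if len(members) >= 2:
            covs[k] = np.cov(members, rowvar=False) + reg * np.eye(d)
        else:
            covs[k] = np.eye(d) * max(reg, 1e-3)
    weights /= weights.sum()
    return weights, means, covs


def em_fit(
    points: np.ndarray,
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
    seed: int = 0,
    participant_id: str = "",
    target: str = "",
    group: str = "",
) -> MixtureModel:
    """Fit a full-covariance Gaussian mixture by EM from a given start.

    EM's log-likelihood is non-decreasing across iterations; iteration stops
    when the per-sample log-likelihood change falls below ``tol`` or after
    ``max_iter`` iterations (in which case the model is flagged as not
    converged). Covariances carry a diagonal regularization of ``reg`` to
    survive duplicated resampled points. Components whose weight collapses
    numerically are dropped with a warning and the rest renormalized.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    weights, means, covs = init
    K = len(weights)
    if X.shape[0] <= K:
        raise ParameterError(f"need more points ({X.shape[0]}) than components ({K})")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        tol=tol,
        reg_covar=reg,
        max_iter=max_iter,
        n_init=1,
        weights_init=np.asarray(weights, dtype=float),
        means_init=np.asarray(means, dtype=float),
        precisions_init=np.linalg.inv(np.asarray(covs, dtype=float)),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ConvergenceWarning surfaces via flag
        gm.fit(X)

    comps = []
    for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_):
        if w < 1e-10:
            logger.warning("dropping degenerate mixture component (weight %.3g)", w)
            continue
        comps.append(GaussianComponent(w, m, c))
    total = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= total

    logL = float(gm.score(X) * X.shape[0])
    model = MixtureModel(
        components=comps,
        log_likelihood=logL,
        n_points=X.shape[0],
        seed=seed,
        participant_id=participant_id,
        target=target,
        group=group,
        converged=bool(gm.converged_),
    )
    model.bic = bic_score(model)
    if not model.converged:
        logger.warning(
            "EM did not converge in %d iterations (K=%d, %s/%s)",
            max_iter, K, participant_id, target,
        )
    return model


def bic_score(model: MixtureModel, points: np.ndarray | None = None) -> float:
    """Bayesian information criterion, k*ln(n) - 2*logL (lower is better).

    The free-parameter count for a K-component full-covariance mixture in
    d dimensions is (K-1) + K*d + K*d*(d+1)/2, i.e. 6K - 1 for d = 2.
    If ``points`` is given the log-likelihood is recomputed on them;
    otherwise the fitted log-likelihood and point count are used.
    """
    K, d = model.K, model.dim
    if points is not None:
        X = np.atleast_2d(np.asarray(points, dtype=float))
        n = X.shape[0]
        logL = float(model.logpdf(X).sum())
    else:
        n = model.n_points
        logL = model.log_likelihood
    if n == 0:
        raise ParameterError("BIC undefined for an empty point set")
    k = (K - 1) + K * d + K * d * (d + 1) // 2
    return k * np.log(n) - 2.0 * logL


def select_gmm(
    points: np.ndarray,
    kmin: int = 2,
    kmax: int = 25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
    patience: int | None = None,
    participant_id: str = "",
    target: str = "",
    group: str = "",
) -> MixtureModel:
    """Fit mixtures for each order in [kmin, kmax] and return the BIC minimum.

    Ties break toward the smaller order. If the point count does not exceed
    ``kmax``, the upper bound is reduced with a warning. With ``patience``
    set, the upward sweep stops early once the BIC has not improved for that
    many consecutive orders (the BIC-versus-order curve is near-convex for
    these point clouds, so this is a search shortcut, not a different
    criterion).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if kmin < 1 or kmax < kmin:
        raise ParameterError(f"invalid order range [{kmin}, {kmax}]")
    if n <= kmax:
        new_kmax = n - 1
        logger.warning("reducing kmax from %d to %d (only %d points)", kmax, new_kmax, n)
        kmax = new_kmax
        if kmax < kmin:
            raise ParameterError(f"too few points ({n}) for kmin={kmin}")

    best: MixtureModel | None = None
    since_improvement = 0
    for K in range(kmin, kmax + 1):
        try:
            init = kmeans_init(X, K, seed, reg=reg)
            model = em_fit(
                X, init, tol=tol, max_iter=max_iter, reg=reg, seed=seed,
                participant_id=participant_id, target=target, group=group,
            )
        except (ParameterError, np.linalg.LinAlgError) as exc:
            logger.warning("order K=%d failed: %s", K, exc)
            continue
        if best is None or model.bic < best.bic:
            best = model
            since_improvement = 0
        else:
            since_improvement += 1
            if patience is not None and since_improvement >= patience:
                logger.debug("stopping order sweep at K=%d (no BIC gain)", K)
                break
    if best is None:
        raise ParameterError("all mixture orders failed to fit")
    return best
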