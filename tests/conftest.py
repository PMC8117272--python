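"""Shared fixtures and mixture-building helpers for the test suite."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

from reachdist import GaussianComponent, MixtureModel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("reachdist").setLevel(logging.ERROR)


def gauss1d(mu: float, var: float, weight: float = 1.0) -> GaussianComponent:
    """A 1-D Gaussian embedded in 2-D (unit variance, zero mean on axis 2).

    KL and Hellinger between two such components reduce exactly to their
    1-D closed forms, because the second axis contributes nothing.
    """
    return GaussianComponent(weight, [mu, 0.0], np.diag([var, 1.0]))


def single(comp: GaussianComponent) -> MixtureModel:
    comp = GaussianComponent(1.0, comp.mean, comp.covariance)
    return MixtureModel([comp], log_likelihood=0.0, n_points=100)


def mixture(weights, means, covs, participant_id="", target="NC") -> MixtureModel:
    comps = [
        GaussianComponent(w, np.asarray(m, float), np.asarray(c, float))
        for w, m, c in zip(weights, means, covs)
    ]
    return MixtureModel(
        comps, log_likelihood=0.0, n_points=100,
        participant_id=participant_id, target=target,
    )


def random_spd(rng: np.random.Generator, scale: float = 0.1) -> np.ndarray:
    a = rng.normal(0, 1, (2, 2))
    return scale * (a @ a.T + 0.5 * np.eye(2))


def sample_mixture(m: MixtureModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n points from a mixture (the Monte-Carlo oracle's sampler)."""
    ks = rng.choice(m.K, size=n, p=m.weights)
    out = np.empty((n, m.dim))
    for k in range(m.K):
        idx = ks == k
        c = m.components[k]
        out[idx] = rng.multivariate_normal(c.mean, c.covariance, int(idx.sum()))
    return out


@pytest.fixture(scope="session")
def full_cohort_result():
    """One full default-cohort pipeline run, shared across tests."""
    import reachdist as rd

    return rd.run_pipeline(rd.RunConfig(seed=1))
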