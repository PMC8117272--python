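"""Closed-form, variational and unscented divergence computations."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import reachdist as rd
from reachdist import GaussianComponent, ParameterError

from conftest import gauss1d, mixture, random_spd, single


class TestGaussianKld:
    def test_identity_is_zero(self):
        a = GaussianComponent(1.0, [0.3, -0.2], [[0.2, 0.05], [0.05, 0.1]])
        assert rd.gaussian_kld(a, a) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "mu_a, var_a, mu_b, var_b, expected",
        [
            (0.0, 1.0, 1.0, 1.0, 0.5),
            (0.0, 1.0, 0.0, 4.0, 0.5 * (0.25 - 1 + np.log(4))),
        ],
    )
    def test_one_dimensional_closed_forms(self, mu_a, var_a, mu_b, var_b, expected):
        kl = rd.gaussian_kld(gauss1d(mu_a, var_a), gauss1d(mu_b, var_b))
        assert kl == pytest.approx(expected, abs=1e-9)
        # independent quadrature oracle on the 1-D marginal
        fa = norm(mu_a, np.sqrt(var_a))
        fb = norm(mu_b, np.sqrt(var_b))
        oracle, _ = quad(
            lambda x: fa.pdf(x) * (fa.logpdf(x) - fb.logpdf(x)), -30, 30
        )
        assert kl == pytest.approx(oracle, abs=1e-6)

    def test_asymmetry_and_nonnegativity(self):
        a, b = gauss1d(0, 1), gauss1d(2, 0.5)
        assert rd.gaussian_kld(a, b) >= 0
        assert rd.gaussian_kld(a, b) != pytest.approx(rd.gaussian_kld(b, a))


class TestVariationalKld:
    def test_zero_for_identical_mixtures(self):
        rng = np.random.default_rng(0)
        f = mixture(
            [0.3, 0.7],
            rng.normal(0, 1, (2, 2)),
            [random_spd(rng), random_spd(rng)],
        )
        assert rd.variational_kld(f, f) == 0.0
        assert rd.bkld(f, f) == 0.0

    def test_collapses_to_component_kl_for_singles(self):
        f, g = single(gauss1d(0, 1)), single(gauss1d(1.5, 2.0))
        expected = rd.gaussian_kld(f.components[0], g.components[0])
        assert rd.variational_kld(f, g) == pytest.approx(expected, abs=1e-12)

    def test_bkld_single_gaussian_pair(self):
        f, g = single(gauss1d(0, 1)), single(gauss1d(1, 1))
        assert rd.bkld(f, g) == pytest.approx(1.0, abs=1e-9)
        assert rd.log_bkld(f, g) == pytest.approx(0.0, abs=1e-9)

    def test_bkld_symmetric_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            f = mixture(
                rng.dirichlet([2, 2]), rng.normal(0, 1, (2, 2)),
                [random_spd(rng), random_spd(rng)],
            )
            g = mixture(
                rng.dirichlet([2, 2, 2]), rng.normal(0, 1, (3, 2)),
                [random_spd(rng) for _ in range(3)],
            )
            assert rd.bkld(f, g) == pytest.approx(rd.bkld(g, f), rel=1e-12)

    def test_log_bkld_floor_for_identical_models(self):
        f = single(gauss1d(0, 1))
        assert rd.log_bkld(f, f) == pytest.approx(np.log(1e-12))


class TestSigmaPoints:
    def test_count_and_weights_for_d2_kappa1(self):
        c = GaussianComponent(1.0, [0.0, 0.0], np.eye(2))
        pts, w = rd.sigma_points(c, kappa=1.0)
        assert pts.shape == (5, 2)
        assert np.allclose(w, [1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6])
        assert w.sum() == pytest.approx(1.0)

    def test_unit_covariance_spread_is_sqrt3(self):
        c = GaussianComponent(1.0, [0.0, 0.0], np.eye(2))
        pts, _ = rd.sigma_points(c, kappa=1.0)
        offsets = pts[1:] - pts[0]
        assert np.allclose(np.abs(offsets).max(axis=1), np.sqrt(3.0))
        assert np.allclose(np.linalg.norm(offsets, axis=1), np.sqrt(3.0))

    def test_points_reproduce_mean_and_covariance(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            c = GaussianComponent(1.0, rng.normal(0, 2, 2), random_spd(rng, 0.5))
            pts, w = rd.sigma_points(c, kappa=1.0)
            mean = w @ pts
            scatter = (w[:, None] * (pts - mean)).T @ (pts - mean)
            assert np.allclose(mean, c.mean, atol=1e-12)
            assert np.allclose(scatter, c.covariance, atol=1e-12)


class TestHellinger:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(3)
        f = mixture(
            [0.4, 0.6], rng.normal(0, 1, (2, 2)),
            [random_spd(rng), random_spd(rng)],
        )
        assert rd.hellinger_unscented(f, f) == pytest.approx(0.0, abs=1e-9)

    def test_single_gaussian_closed_form(self):
        f, g = single(gauss1d(0, 1)), single(gauss1d(1, 1))
        expected = np.sqrt(1 - np.exp(-1 / 8))
        closed = rd.gaussian_hellinger(f.components[0], g.components[0])
        assert closed == pytest.approx(expected, abs=1e-12)
        # the 5-point unscented quadrature carries a small, known bias
        assert rd.hellinger_unscented(f, g) == pytest.approx(expected, abs=2e-3)

    def test_distant_gaussians_saturate(self):
        f, g = single(gauss1d(0, 1)), single(gauss1d(20, 1))
        assert rd.hellinger_unscented(f, g) >= 0.99
        assert rd.hellinger_unscented(f, g) <= 1.0

    def test_symmetric_by_construction(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            f = mixture(
                rng.dirichlet([3, 3]), rng.normal(0, 0.5, (2, 2)),
                [random_spd(rng), random_spd(rng)],
            )
            g = mixture(
                rng.dirichlet([3, 3]), rng.normal(0, 0.5, (2, 2)),
                [random_spd(rng), random_spd(rng)],
            )
            assert rd.hellinger_unscented(f, g) == rd.hellinger_unscented(g, f)

    def test_component_permutation_invariance(self):
        rng = np.random.default_rng(5)
        w = [0.25, 0.35, 0.4]
        means = rng.normal(0, 1, (3, 2))
        covs = [random_spd(rng) for _ in range(3)]
        f = mixture(w, means, covs)
        perm = [2, 0, 1]
        fp = mixture([w[i] for i in perm], means[perm], [covs[i] for i in perm])
        g = mixture([0.5, 0.5], rng.normal(0, 1, (2, 2)),
                    [random_spd(rng), random_spd(rng)])
        assert rd.hellinger_unscented(f, g) == pytest.approx(
            rd.hellinger_unscented(fp, g), abs=1e-12
        )
        assert rd.bkld(f, g) == pytest.approx(rd.bkld(fp, g), abs=1e-12)

    def test_both_distances_grow_with_separation(self):
        f = single(gauss1d(0, 1))
        shifts = [0.5, 1.0, 2.0, 4.0, 8.0]
        hds = [rd.hellinger_unscented(f, single(gauss1d(s, 1))) for s in shifts]
        bklds = [rd.bkld(f, single(gauss1d(s, 1))) for s in shifts]
        assert all(np.diff(hds) > 0)
        assert all(np.diff(bklds) > 0)


class TestNearestNeighbor:
    def _models(self):
        refs = [
            single(gauss1d(3.0, 1.0)),
            single(gauss1d(1.0, 1.0)),
            single(gauss1d(2.0, 1.0)),
        ]
        for i, r in enumerate(refs):
            r.participant_id = f"C{i}"
        subject = single(gauss1d(0.0, 1.0))
        subject.participant_id = "S0"
        return subject, refs

    def test_minimum_and_argmin(self):
        subject, refs = self._models()
        res = rd.nearest_neighbor_distance(subject, refs, "BKLD")
        per_ref = dict(res.all_ref_values)
        assert res.value == min(per_ref.values())
        assert res.nearest_ref_id == "C1"
        assert res.value == pytest.approx(rd.bkld(subject, refs[1]))

    def test_self_in_refs_without_exclusion_gives_zero(self):
        subject, refs = self._models()
        clone = single(gauss1d(0.0, 1.0))
        clone.participant_id = "S0"
        res = rd.nearest_neighbor_distance(
            subject, refs + [clone], "BKLD", exclude_self=False
        )
        assert res.value == 0.0
        res_loo = rd.nearest_neighbor_distance(subject, refs + [clone], "BKLD")
        assert res_loo.value > 0.0
        assert res_loo.nearest_ref_id != "S0"

    def test_tie_keeps_first_reference(self):
        subject, _ = self._models()
        twin_a = single(gauss1d(1.0, 1.0))
        twin_a.participant_id = "CA"
        twin_b = single(gauss1d(1.0, 1.0))
        twin_b.participant_id = "CB"
        res = rd.nearest_neighbor_distance(subject, [twin_a, twin_b], "HD")
        assert res.nearest_ref_id == "CA"

    def test_error_cases(self):
        subject, refs = self._models()
        with pytest.raises(ParameterError):
            rd.nearest_neighbor_distance(subject, [], "HD")
        with pytest.raises(ParameterError):
            rd.nearest_neighbor_distance(subject, refs, "L2")
        refs[0].target = "FC"
        with pytest.raises(ParameterError):
            rd.nearest_neighbor_distance(subject, refs, "HD")
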