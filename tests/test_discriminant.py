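import numpy as np
import pytest

from pfda_audit.datasets import ClassPartition, ClassRule, TaxonRecord
from pfda_audit.discriminant import (
    FitError,
    fit_lda,
    fit_pfda,
    gaussian_pdf,
    pwrong,
)
from pfda_audit.phylo import TreeEnsemble, pure_birth_tree, random_ensemble
from pfda_audit.synthetic import gen_two_class


def mahalanobis_oracle(X, y, query):
    """Brute-force nearest-centroid classification in the pooled metric."""
    X, y = np.asarray(X, float), np.asarray(y)
    mu1, mu2 = X[y == 1].mean(0), X[y == 2].mean(0)
    R1, R2 = X[y == 1] - mu1, X[y == 2] - mu2
    S = (R1.T @ R1 + R2.T @ R2) / (len(X) - 2)
    Si = np.linalg.inv(S)
    out = []
    for q in np.atleast_2d(query):
        d1 = (q - mu1) @ Si @ (q - mu1)
        d2 = (q - mu2) @ Si @ (q - mu2)
        out.append(1 if d1 < d2 else 2)
    return np.array(out)


class TestGaussianPdf:
    def test_identity_covariance_at_centroid(self):
        assert gaussian_pdf([0, 0], [0, 0], np.eye(2)) == pytest.approx(1 / (2 * np.pi))

    def test_equal_mahalanobis_gives_equal_density(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu1, mu2 = np.array([1.0, 0.0]), np.array([-1.0, 0.0])
        # boundary points: mid + t*v with v orthogonal to Sigma^-1 (mu2-mu1)
        w = np.linalg.solve(sigma, mu2 - mu1)
        v = np.array([-w[1], w[0]])
        for t in (-2.0, 0.0, 1.3):
            p = 0.5 * (mu1 + mu2) + t * v
            assert gaussian_pdf(p, mu1, sigma) == pytest.approx(
                gaussian_pdf(p, mu2, sigma)
            )

    def test_total_mass_one_by_grid_integration(self):
        sigma = np.array([[1.3, -0.4], [-0.4, 0.8]])
        mu = np.array([0.5, -0.2])
        g = np.linspace(-8, 8, 401)
        xx, yy = np.meshgrid(g + mu[0], g + mu[1])
        vals = np.array(
            [gaussian_pdf(p, mu, sigma) for p in np.c_[xx.ravel(), yy.ravel()]]
        )
        h = g[1] - g[0]
        assert vals.sum() * h * h == pytest.approx(1.0, abs=1e-4)

    def test_singular_sigma_rejected(self):
        with pytest.raises(FitError):
            gaussian_pdf([0, 0], [0, 0], np.ones((2, 2)))


class TestPwrong:
    @pytest.mark.parametrize(
        "d,sigma,expected,tol",
        [
            (1.96, 1.0, 0.025, 1e-4),
            (2.33, 1.0, 0.01, 1e-4),
            (1.7, 1.414, 0.115, 5e-4),
            (0.0, 1.0, 0.5, 1e-12),
        ],
    )
    def test_values(self, d, sigma, expected, tol):
        assert pwrong(d, sigma) == pytest.approx(expected, abs=tol)

    def test_domain(self):
        with pytest.raises(ValueError):
            pwrong(-1, 1)
        with pytest.raises(ValueError):
            pwrong(1, 0)


class TestFitLda:
    def test_symmetric_clouds_boundary_is_y_equals_x(self):
        X, y = gen_two_class(4000, 0.55, seed=0)
        fit = fit_lda(X, y)
        # boundary passes near the origin with direction ~ (1, 1)/sqrt(2)
        b0, d = fit.boundary_point, fit.boundary_direction
        assert abs(b0[0] - b0[1]) < 0.05  # on y = x up to sampling noise
        assert abs(abs(d @ [1, 1] / np.sqrt(2)) - 1) < 1e-3

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_mahalanobis_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 6, 2)
        X = np.vstack([rng.normal(0, 1, (n1, 2)), rng.normal(1.5, 1, (n2, 2))])
        y = np.r_[np.ones(n1, int), np.full(n2, 2)]
        fit = fit_lda(X, y)
        Q = rng.normal(0.5, 2, (25, 2))
        assert np.array_equal(fit.classify(Q), mahalanobis_oracle(X, y, Q))

    def test_identical_centroids_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 2))
        X = np.vstack([A, A])
        y = np.r_[np.ones(8, int), np.full(8, 2)]
        with pytest.raises(FitError):
            fit_lda(X, y)

    def test_training_error_converges_to_theory(self):
        X, y = gen_two_class(5000, 1.414, seed=4)
        fit = fit_lda(X, y)
        acc = np.mean(fit.predictions == y)
        assert acc == pytest.approx(1 - pwrong(2.4 / np.sqrt(2), 1.414), abs=0.01)
        # training errors are nonzero in expectation for finite separation
        assert acc < 1.0

    def test_boundary_invariant_under_common_affine_rescaling(self):
        X, y = gen_two_class(300, 1.0, seed=5)
        fit = fit_lda(X, y)
        A = np.array([[2.0, 0.3], [0.0, 0.5]])
        shift = np.array([3.0, -1.0])
        fit2 = fit_lda(X @ A.T + shift, y)
        Q = np.random.default_rng(6).normal(0, 2, (40, 2))
        assert np.array_equal(fit.classify(Q), fit2.classify(Q @ A.T + shift))

    def test_posterior_monotone_along_centroid_axis(self):
        X, y = gen_two_class(400, 1.0, seed=7)
        fit = fit_lda(X, y)
        mu1, mu2 = fit.model.mu1, fit.model.mu2
        ts = np.linspace(-1, 2, 50)
        pts = mu1 + np.outer(ts, mu2 - mu1)
        p2 = fit.posterior2(pts)
        assert np.all(np.diff(p2) >= -1e-12)


def _partition_from_points(X, y, prefix="s"):
    recs1 = [
        TaxonRecord(f"{prefix}1_{i}", 10 ** float(x[0]) if x[0] < 3 else 1e3, _cg(x[1]), "0", "0")
        for i, x in enumerate(X[y == 1])
    ]
    recs2 = [
        TaxonRecord(f"{prefix}2_{i}", 10 ** float(x[0]) if x[0] < 3 else 1e3, _cg(x[1]), "0", "2")
        for i, x in enumerate(X[y == 2])
    ]
    return ClassPartition(recs1, recs2, ClassRule("F0D0_vs_F0D2"))


def _cg(v, lo=0.05, hi=1.0):
    return float(np.clip(0.5 + 0.1 * v, lo, hi))


class TestFitPfda:
    def _setup(self, n=12, seed=2):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal([1.0, -1.0], 0.4, (n, 2)), rng.normal([1.3, 1.0], 0.4, (n, 2))]
        )
        y = np.r_[np.ones(n, int), np.full(n, 2)]
        part = _partition_from_points(X, y)
        tree = pure_birth_tree(2 * n + 1, seed=seed)
        leaves = list(tree.leaf_node_iter())
        for leaf, rec in zip(leaves, part.records):
            leaf.taxon.label = rec.taxon_id
        leaves[-1].taxon.label = "probe"
        return part, tree

    def test_one_posterior_sample_per_tree(self):
        part, tree = self._setup()
        ens = random_ensemble(tree, n=100, seed=3)
        test = [TaxonRecord("probe", 15.0, 0.9, "0", "unknown", role="test")]
        summ, mets = fit_pfda(part, ens, test, lam=0.05)
        assert len(summ[0].p2_samples) == 100
        assert len(mets) == 100
        lo, hi = summ[0].ci95
        assert lo <= summ[0].median_p2 <= hi
        assert summ[0].classified_d2_count == int(np.sum(summ[0].p2_samples >= 0.5))

    def test_lambda_zero_equals_plain_lda(self):
        part, tree = self._setup()
        test = [TaxonRecord("probe", 15.0, 0.9, "0", "unknown", role="test")]
        summ, _ = fit_pfda(part, TreeEnsemble([tree], 0), test, lam=0.0)
        X = np.array([[r.log_md, r.cg] for r in part.records])
        y = np.array(part.labels)
        p_plain = fit_lda(X, y).posterior2([[np.log10(15.0), 0.9]])[0]
        assert abs(summ[0].p2_samples[0] - p_plain) < 1e-8

    def test_separated_classes_centroid_test_point_is_certain(self):
        rng = np.random.default_rng(11)
        n = 10
        X = np.vstack(
            [rng.normal([0.6, -2.0], 0.2, (n, 2)), rng.normal([1.4, 2.0], 0.2, (n, 2))]
        )
        y = np.r_[np.ones(n, int), np.full(n, 2)]
        part = _partition_from_points(X, y, prefix="w")
        tree = pure_birth_tree(2 * n + 1, seed=12)
        leaves = list(tree.leaf_node_iter())
        for leaf, rec in zip(leaves, part.records):
            leaf.taxon.label = rec.taxon_id
        leaves[-1].taxon.label = "center2"
        mu2 = X[y == 2].mean(0)
        test = [
            TaxonRecord("center2", 10 ** float(mu2[0]), _cg(mu2[1]), "0", "unknown", role="test")
        ]
        summ, _ = fit_pfda(part, random_ensemble(tree, 20, seed=13), test, lam=0.05)
        assert summ[0].median_p2 > 0.99

    def test_missing_taxon_named_in_error(self):
        part, tree = self._setup()
        test = [TaxonRecord("not_in_tree", 15.0, 0.9, "0", "unknown", role="test")]
        with pytest.raises(Exception, match="not_in_tree"):
            fit_pfda(part, TreeEnsemble([tree], 0), test, lam=0.0)
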