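"""Two-class linear discriminant core and its phylogenetic wrapper.

Linear discriminant analysis (LDA) assumes each class k is bivariate normal
with its own centroid mu_k but a single shared covariance Sigma.  A point is
assigned to the class whose centroid is nearest in the Mahalanobis metric of
the pooled within-class covariance; the locus of equal distance — the
decision boundary — is then a straight line.  With equal priors the
posterior probability of class 2 is a logistic function of the signed
distance along the single discriminant axis.

For two bivariate normals with Sigma = sigma^2·I whose centroids sit a
distance d from the boundary, the exact misclassification probability is

    P_wrong = 1/2 · erfc(d / (sigma·sqrt(2))),

so classification error never vanishes for finite d/sigma, no matter how
large the training set: as n grows, the empirical training error converges
to P_wrong rather than to zero.

The phylogenetic variant (pFDA with a linear boundary, i.e. phylogenetic
LDA) GLS-whitens the stacked training+test trait matrix with the inverse
Cholesky factor of the lambda-scaled Brownian tree covariance before
fitting; at lambda -> 0 it reduces to ordinary LDA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .datasets import ClassPartition, TaxonRecord
from .metrics import ConfusionMatrix, MetricSet, confusion, metrics
from .phylo import (
    TreeEnsemble,
    apply_lambda,
    bm_covariance,
    optimize_lambda,
    prune_to,
)

__all__ = [
    "FitError",
    "GaussianClassModel",
    "DiscriminantFit",
    "PosteriorSummary",
    "gaussian_pdf",
    "fit_lda",
    "pwrong",
    "fit_pfda",
]


class FitError(Exception):
    """Degenerate input for discriminant fitting."""


def gaussian_pdf(p, mu, sigma) -> float:
    """Bivariate normal density at ``p`` for centroid ``mu``, covariance ``sigma``."""
    p = np.asarray(p, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    det = np.linalg.det(sigma)
    if det <= 0:
        raise FitError("covariance must be positive definite")
    diff = p - mu
    maha2 = diff @ np.linalg.solve(sigma, diff)
    return float(np.exp(-0.5 * maha2) / (2 * np.pi * np.sqrt(det)))


def pwrong(d: float, sigma: float) -> float:
    """Exact probability of landing on the wrong side of the boundary."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(0.5 * erfc(d / (sigma * math.sqrt(2.0))))


@dataclass
class GaussianClassModel:
    """Shared-covariance two-class Gaussian model (centroids + pooled Sigma)."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma_pooled: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        self.mu1 = np.asarray(self.mu1, float)
        self.mu2 = np.asarray(self.mu2, float)
        self.sigma_pooled = np.asarray(self.sigma_pooled, float)
        if np.allclose(self.mu1, self.mu2):
            raise FitError("class centroids coincide; no discriminant direction")
        if abs(sum(self.priors) - 1.0) > 1e-9 or min(self.priors) <= 0:
            raise FitError("priors must be positive and sum to 1")


@dataclass
class DiscriminantFit:
    """A fitted two-class LDA: boundary, scores and posteriors."""

    model: GaussianClassModel
    boundary_point: np.ndarray      # a point on the decision boundary
    boundary_direction: np.ndarray  # unit vector along the boundary line
    scores: np.ndarray              # 1-D discriminant values of training rows
    posteriors: np.ndarray          # training P(class 2 | x)
    predictions: np.ndarray         # training class labels in {1, 2}
    _w: np.ndarray = field(repr=False, default=None)
    _mid: np.ndarray = field(repr=False, default=None)
    _scale: float = field(repr=False, default=1.0)

    def score(self, points) -> np.ndarray:
        """Discriminant scores: unit within-class variance along the axis,
        zero at the midpoint between centroids."""
        P = np.atleast_2d(np.asarray(points, float))
        return (P - self._mid) @ self._w / self._scale

    def posterior2(self, points) -> np.ndarray:
        """P(class 2 | x) from the shared-covariance density ratio."""
        P = np.atleast_2d(np.asarray(points, float))
        logit = (P - self._mid) @ self._w + math.log(
            self.model.priors[1] / self.model.priors[0]
        )
        return 1.0 / (1.0 + np.exp(-logit))

    def classify(self, points, threshold: float = 0.5) -> np.ndarray:
        return np.where(self.posterior2(points) >= threshold, 2, 1)


def fit_lda(points, labels, priors: tuple[float, float] = (0.5, 0.5)) -> DiscriminantFit:
    """Fit a two-class LDA with the unbiased pooled covariance (divisor n-2).

    ``labels`` are 1/2.  Classification of any point equals
    nearest-centroid in the pooled Mahalanobis metric (for equal priors).
    """
    X = np.atleast_2d(np.asarray(points, float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("points and labels differ in length")
    X1, X2 = X[y == 1], X[y == 2]
    if len(X1) < 3 or len(X2) < 3:
        raise FitError("each class needs at least 3 points")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    R1, R2 = X1 - mu1, X2 - mu2
    S = (R1.T @ R1 + R2.T @ R2) / (len(X) - 2)
    if np.linalg.det(S) <= 1e-300:
        raise FitError("pooled covariance is singular (collinear points)")
    model = GaussianClassModel(mu1, mu2, S, priors)
    w = np.linalg.solve(S, mu2 - mu1)
    mid = 0.5 * (mu1 + mu2)
    scale = math.sqrt(w @ S @ w)  # w'Sw: within-class variance of w'x
    # boundary: w'(x - b0) = log(pi1/pi2); param point + direction
    offset = math.log(priors[0] / priors[1])
    b0 = mid + offset * w / (w @ w)
    direction = np.array([-w[1], w[0]]) if len(w) == 2 else None
    if direction is not None:
        direction = direction / np.linalg.norm(direction)
    fit = DiscriminantFit(
        model=model,
        boundary_point=b0,
        boundary_direction=direction,
        scores=None,
        posteriors=None,
        predictions=None,
        _w=w,
        _mid=mid,
        _scale=scale,
    )
    fit.scores = fit.score(X)
    fit.posteriors = fit.posterior2(X)
    fit.predictions = fit.classify(X)
    return fit


@dataclass
class PosteriorSummary:
    """Per-taxon distribution of class-2 posteriors across random trees."""

    taxon_id: str
    p2_samples: np.ndarray
    threshold: float = 0.5

    @property
    def median_p2(self) -> float:
        return float(np.median(self.p2_samples))

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.p2_samples, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def classified_d2_count(self) -> int:
        return int(np.sum(self.p2_samples >= self.threshold))


def _trait_matrix(records: list[TaxonRecord]) -> np.ndarray:
    return np.array([[r.log_md, r.cg] for r in records])


def _pfda_one_tree(
    Z: np.ndarray,
    gw: np.ndarray,
    labels: np.ndarray,
    ntr: int,
    threshold: float,
    priors: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, ConfusionMatrix]:
    """Discriminant on whitened rows Z = W·[1 | X] (train rows first).

    Two-class flexible discriminant analysis via optimal scoring: the
    whitened class indicator ``gw`` is regressed on the whitened design
    (the whitened intercept column replaces the usual constant — this is
    what makes the fit a GLS fit), giving the single discriminant variate.
    A one-dimensional shared-variance Gaussian model on the training
    variates then yields classifications and class-2 posteriors.
    """
    ztr = Z[:ntr]
    b, *_ = np.linalg.lstsq(ztr, gw, rcond=None)
    eta = Z @ b
    e1, e2 = eta[:ntr][labels == 1], eta[:ntr][labels == 2]
    m1, m2 = e1.mean(), e2.mean()
    if np.isclose(m1, m2):
        raise FitError("degenerate discriminant: class variate means coincide")
    s2 = (np.sum((e1 - m1) ** 2) + np.sum((e2 - m2) ** 2)) / (ntr - 2)
    logit = (m2 - m1) / s2 * (eta - 0.5 * (m1 + m2)) + math.log(priors[1] / priors[0])
    p2 = 1.0 / (1.0 + np.exp(-logit))
    pred_train = np.where(p2[:ntr] >= threshold, 2, 1)
    return p2, eta, confusion(labels, pred_train)


def fit_pfda(
    part: ClassPartition,
    ensemble: TreeEnsemble,
    test: list[TaxonRecord] | None = None,
    threshold: float = 0.5,
    lam: float | None = None,
    priors: tuple[float, float] = (0.5, 0.5),
    return_scores: bool = False,
):
    """Phylogenetic LDA across a tree ensemble.

    For each tree: prune to the analysis taxa, build the Brownian
    covariance, estimate Pagel's lambda on the joint (training + test)
    predictor matrix unless ``lam`` is given, whiten the design (intercept
    included) and the class indicator jointly with the inverse Cholesky
    factor of C(lambda), and fit the two-class discriminant by optimal
    scoring on the whitened rows; test rows are whitened jointly with the
    training rows and scored on the same discriminant variate.  Returns one
    posterior sample per tree per test taxon plus the per-tree training
    metric set (and the per-tree discriminant variates when
    ``return_scores`` is set).
    """
    test = list(test or [])
    train = part.records
    labels = np.asarray(part.labels)
    taxa = [r.taxon_id for r in train] + [r.taxon_id for r in test]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids across training and test records")
    X = np.vstack([_trait_matrix(train)] + ([_trait_matrix(test)] if test else []))
    ntr = len(train)

    A = np.hstack([np.ones((len(X), 1)), X])
    g = np.where(labels == 2, 1.0, -1.0)

    p2 = np.empty((len(test), len(ensemble)))
    per_tree_metrics: list[MetricSet] = []
    scores: list[np.ndarray] = []
    for k, tree in enumerate(ensemble):
        sub = prune_to(tree, taxa)
        cov = bm_covariance(sub, taxa)
        lam_k = optimize_lambda(X, cov) if lam is None else lam
        W = np.linalg.inv(
            np.linalg.cholesky(apply_lambda(cov, lam_k).matrix)
        )
        Z = W @ A
        # W is lower triangular and training rows come first, so the train
        # block of W whitens the training response on its own
        gw = W[:ntr, :ntr] @ g
        p2_k, eta, cm = _pfda_one_tree(Z, gw, labels, ntr, threshold, priors)
        per_tree_metrics.append(metrics(cm))
        scores.append(eta)
        if test:
            p2[:, k] = p2_k[ntr:]
    summaries = [
        PosteriorSummary(r.taxon_id, p2[i].copy(), threshold)
        for i, r in enumerate(test)
    ]
    if return_scores:
        return summaries, per_tree_metrics, scores
    return summaries, per_tree_metrics
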