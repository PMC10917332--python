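"""Distributional prerequisites of the discriminant, audited.

A shared-covariance Gaussian discriminant is only as good as its
assumptions: each class's discriminant scores should be normal, with a
standard deviation *pooled* across the two classes.  This module fits a
battery of candidate families to score samples by maximum likelihood and
ranks them by AICc (small-sample-corrected Akaike information criterion),
converting Akaike weights into normalized probabilities P_dist; it tests
variance equality with three tests robust to non-normality
(Brown-Forsythe, Levene, Conover squared ranks); and it measures clustering
tendency of the raw 2-D point sets with the Hopkins statistic, whose null
(spatial uniformity) distribution is Beta(m, m) for m probe points and is
additionally calibrated by Monte Carlo.

If a class is statistically indistinguishable from a uniform point cloud,
its "centroid" carries no information and discriminant classification is
meaningless — which is precisely what these diagnostics are built to
detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, cKDTree, Delaunay
from sklearn.mixture import GaussianMixture

__all__ = [
    "CandidateFit",
    "FitComparison",
    "HopkinsResult",
    "fit_candidates",
    "joint_normality_probability",
    "variance_tests",
    "conover_squared_ranks",
    "hopkins",
    "kde_and_qq",
    "DEFAULT_FAMILIES",
]

DEFAULT_FAMILIES = (
    "pooled_normal",
    "normal",
    "uniform",
    "weibull3",
    "logistic",
    "normal_mixture2",
    "normal_mixture3",
    "uniform_normal_mixture",
)


@dataclass
class CandidateFit:
    family: str
    params: dict
    k: int              # free-parameter count charged to AICc
    loglik: float
    converged: bool = True


@dataclass
class FitComparison:
    """Per-family AICc comparison table."""

    fits: list[CandidateFit]
    n: int

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            aicc = _aicc(f.loglik, f.k, self.n)
            rows.append(
                {
                    "family": f.family,
                    "k": f.k,
                    "loglik": f.loglik,
                    "AICc": aicc,
                    "converged": f.converged,
                }
            )
        df = pd.DataFrame(rows)
        ok = df["converged"]
        df["dAICc"] = df["AICc"] - df.loc[ok, "AICc"].min()
        df["W"] = np.where(ok, np.exp(-df["dAICc"] / 2.0), np.nan)
        df["P_dist"] = df["W"] / df.loc[ok, "W"].sum()
        return df

    def p_dist(self, family: str) -> float:
        df = self.table()
        return float(df.loc[df["family"] == family, "P_dist"].iloc[0])

    def best_family(self) -> str:
        df = self.table()
        return str(df.loc[df["dAICc"].idxmin(), "family"])


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_family(x: np.ndarray, family: str, pooled_sigma: float | None, seed: int) -> CandidateFit:
    n = len(x)
    if family == "normal":
        mu, sd = x.mean(), x.std(ddof=0)
        ll = float(np.sum(stats.norm.logpdf(x, mu, sd)))
        return CandidateFit(family, {"mean": mu, "sd": sd}, 2, ll)
    if family == "pooled_normal":
        if pooled_sigma is None:
            raise ValueError("pooled_normal requires pooled_sigma")
        mu = x.mean()
        ll = float(np.sum(stats.norm.logpdf(x, mu, pooled_sigma)))
        # the pooled sd is estimated from both classes jointly; charge it
        # here as a parameter so AICc comparisons stay honest
        return CandidateFit(family, {"mean": mu, "sd": pooled_sigma}, 2, ll)
    if family == "uniform":
        lo, hi = x.min(), x.max()
        ll = -n * math.log(hi - lo) if hi > lo else math.inf
        return CandidateFit(family, {"lo": lo, "hi": hi}, 2, ll)
    if family == "logistic":
        loc, scale = stats.logistic.fit(x)
        ll = float(np.sum(stats.logistic.logpdf(x, loc, scale)))
        return CandidateFit(family, {"loc": loc, "scale": scale}, 2, ll)
    if family == "weibull3":
        c, loc, scale = stats.weibull_min.fit(x)
        ll = float(np.sum(stats.weibull_min.logpdf(x, c, loc, scale)))
        ok = np.isfinite(ll)
        return CandidateFit(
            family, {"shape": c, "loc": loc, "scale": scale}, 3, ll if ok else -math.inf, ok
        )
    if family in ("normal_mixture2", "normal_mixture3"):
        c = 2 if family.endswith("2") else 3
        gm = GaussianMixture(
            n_components=c, covariance_type="full", random_state=seed, n_init=5,
            reg_covar=1e-6,
        ).fit(x.reshape(-1, 1))
        ll = float(gm.score(x.reshape(-1, 1)) * n)
        params = {
            "weights": gm.weights_.tolist(),
            "means": gm.means_.ravel().tolist(),
            "sds": np.sqrt(gm.covariances_.ravel()).tolist(),
        }
        return CandidateFit(family, params, 3 * c - 1, ll, bool(gm.converged_))
    if family == "uniform_normal_mixture":
        return _fit_uniform_normal_mixture(x)
    raise ValueError(f"unknown family {family!r}")


def _fit_uniform_normal_mixture(x: np.ndarray, n_iter: int = 300) -> CandidateFit:
    """EM for w·U(lo, hi) + (1-w)·N(mu, sd); support fixed at the data range."""
    n = len(x)
    lo, hi = x.min(), x.max()
    du = 1.0 / (hi - lo) if hi > lo else math.inf
    w, mu, sd = 0.5, x.mean(), x.std(ddof=0) / 2
    ll_old = -math.inf
    converged = False
    for _ in range(n_iter):
        fu = np.full(n, du)
        fn = stats.norm.pdf(x, mu, max(sd, 1e-9))
        tot = w * fu + (1 - w) * fn
        tot = np.maximum(tot, 1e-300)
        r = w * fu / tot
        w = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        wn = (1 - r)
        mu = float(np.sum(wn * x) / np.sum(wn))
        sd = float(np.sqrt(np.sum(wn * (x - mu) ** 2) / np.sum(wn)))
        ll = float(np.sum(np.log(tot)))
        if abs(ll - ll_old) < 1e-9:
            converged = True
            break
        ll_old = ll
    ll = float(
        np.sum(np.log(np.maximum(w * du + (1 - w) * stats.norm.pdf(x, mu, max(sd, 1e-9)), 1e-300)))
    )
    # parameters: weight, uniform lo/hi, normal mu/sd -> 5
    return CandidateFit(
        "uniform_normal_mixture",
        {"w_uniform": w, "lo": lo, "hi": hi, "mean": mu, "sd": sd},
        5,
        ll,
        converged,
    )


def fit_candidates(
    values,
    families=DEFAULT_FAMILIES,
    pooled_sigma: float | None = None,
    seed: int = 0,
) -> FitComparison:
    """Maximum-likelihood fits of candidate families to score samples.

    ``pooled_sigma`` supplies the across-class pooled standard deviation
    required by the ``pooled_normal`` family (the discriminant's own
    assumption); omit it to drop that family.
    """
    x = np.asarray(values, float)
    if len(x) < 20:
        raise ValueError("need at least 20 values for distribution comparison")
    if not families:
        raise ValueError("candidate list is empty")
    fams = [
        f for f in families if not (f == "pooled_normal" and pooled_sigma is None)
    ]
    fits = []
    for fam in fams:
        try:
            fits.append(_fit_family(x, fam, pooled_sigma, seed))
        except Exception:
            fits.append(CandidateFit(fam, {}, 0, -math.inf, converged=False))
    return FitComparison(fits, len(x))


def joint_normality_probability(fit_a: FitComparison, fit_b: FitComparison) -> float:
    """Probability both classes satisfy the pooled-normal assumption:
    the product of the two pooled-normal P_dist values."""
    return fit_a.p_dist("pooled_normal") * fit_b.p_dist("pooled_normal")


def conover_squared_ranks(a, b) -> tuple[float, float]:
    """Conover's squared-ranks test for equal variances (normal approximation).

    Absolute deviations from each group's mean are ranked jointly; the
    statistic is the standardized sum of squared ranks in the first group.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u = np.concatenate([np.abs(a - a.mean()), np.abs(b - b.mean())])
    r = stats.rankdata(u) ** 2
    n1, n = len(a), len(a) + len(b)
    t = r[:n1].sum()
    rbar = r.mean()
    var = n1 * (n - n1) / (n * (n - 1)) * (np.sum(r**2) - n * rbar**2)
    z = (t - n1 * rbar) / math.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def variance_tests(group_a, group_b) -> dict[str, tuple[float, float]]:
    """Three variance-equivalence tests robust to non-normality.

    Returns ``{'brown_forsythe': (stat, p), 'levene': ..., 'conover': ...}``;
    the null hypothesis of each is equal variances.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs at least 5 values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate zero-variance group")
    bf = stats.levene(a, b, center="median")
    lv = stats.levene(a, b, center="mean")
    cn = conover_squared_ranks(a, b)
    return {
        "brown_forsythe": (float(bf.statistic), float(bf.pvalue)),
        "levene": (float(lv.statistic), float(lv.pvalue)),
        "conover": cn,
    }


@dataclass
class HopkinsResult:
    variant: str
    H: float                 # mean over `reps` subsample trials
    m: int                   # probe points per trial
    p_beta: float            # from the Beta(m, m) single-trial null
    p_mc: float | None       # from the Monte Carlo null of mean-H (if run)
    reps: int
    mc_trials: int


def _hopkins_once(
    pts: np.ndarray,
    m: int,
    rng: np.random.Generator,
    exponent: int,
    window: str,
    hull: Delaunay | None,
    bbox: tuple[np.ndarray, np.ndarray],
    periodic: bool,
) -> float:
    n = len(pts)
    lo, span = bbox
    # probe origins: uniform in the sampling window
    probes = np.empty((m, pts.shape[1]))
    got = 0
    while got < m:
        cand = lo + span * rng.random((4 * m, pts.shape[1]))
        if window == "hull":
            cand = cand[hull.find_simplex(cand) >= 0]
        take = min(m - got, len(cand))
        probes[got : got + take] = cand[:take]
        got += take
    marks = rng.choice(n, size=m, replace=False)
    rest = np.delete(np.arange(n), marks)
    # both distance sets face the same reference intensity: the marked
    # points are removed from the reference set, which is what makes the
    # single-trial null exactly Beta(m, m) in an edge-free window
    if periodic:
        box = span * (1 + 1e-9)
        tree = cKDTree(np.mod(pts[rest] - lo, box), boxsize=box)
        u, _ = tree.query(np.mod(probes - lo, box), k=1)
        w, _ = tree.query(np.mod(pts[marks] - lo, box), k=1)
    else:
        tree = cKDTree(pts[rest])
        u, _ = tree.query(probes, k=1)
        w, _ = tree.query(pts[marks], k=1)
    ue = u**exponent
    we = w**exponent
    return float(ue.sum() / (ue.sum() + we.sum()))


def hopkins(
    points,
    variant: str = "original",
    frac: float = 0.2,
    reps: int = 100,
    seed: int = 0,
    window: str = "bbox",
    bounds: tuple | None = None,
    periodic: bool = False,
    mc_trials: int = 10_000,
) -> HopkinsResult:
    """Hopkins clustering-tendency test on a 2-D point set.

    ``H`` compares nearest-neighbour distances of uniform probe points
    against those of real points: H ≈ 0.5 for spatial uniformity and -> 1
    for clustered data.  Variants: ``original`` (distances raised to the
    data dimension, bounding-box window — the form whose single-trial null
    is Beta(m, m)); ``lj`` (Lawson-Jurs: raw first-power distances);
    ``fpm`` (Fernandez Pierna-Massart: dimension exponent with probe points
    confined to the data's convex hull).  The m marked data points are
    removed from the reference set so probe and mark distances face the
    same point intensity.  H is averaged over ``reps`` random 20%
    subsamples; p-values are one-sided toward clustering (large H), from
    the Beta(m, m) law and, when ``mc_trials`` > 0, from an empirical null
    of uniform point sets matched in size and window.

    ``bounds`` supplies a known sampling window as (lo, hi) coordinate
    arrays (default: the data's bounding box); ``periodic`` uses toroidal
    distances within that window — the edge-free setting in which the
    single-trial null is exactly Beta(m, m).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    n, dim = pts.shape
    if n < 15:
        raise ValueError("need at least 15 points")
    if variant not in ("original", "lj", "fpm"):
        raise ValueError(f"unknown Hopkins variant {variant!r}")
    rng = np.random.default_rng(seed)
    # duplicate points give zero NN distances; jitter minutely
    if len(np.unique(pts, axis=0)) < n:
        scale = pts.std(axis=0).mean() or 1.0
        pts = pts + rng.normal(0, 1e-9 * scale, pts.shape)
    exponent = dim if variant in ("original", "fpm") else 1
    win = "hull" if (variant == "fpm" or window == "hull") else "bbox"
    hull = Delaunay(pts[ConvexHull(pts).vertices]) if win == "hull" else None
    if bounds is not None:
        lo = np.asarray(bounds[0], float)
        span = np.asarray(bounds[1], float) - lo
    else:
        lo = pts.min(axis=0)
        span = pts.max(axis=0) - lo
    m = max(2, int(round(frac * n)))

    H = float(
        np.mean(
            [
                _hopkins_once(pts, m, rng, exponent, win, hull, (lo, span), periodic)
                for _ in range(reps)
            ]
        )
    )
    p_beta = float(stats.beta.sf(H, m, m))
    p_mc = None
    if mc_trials > 0:
        null = np.empty(mc_trials)
        for t in range(mc_trials):
            if win == "hull":
                upts = np.empty((n, dim))
                got = 0
                while got < n:
                    cand = lo + span * rng.random((2 * n, dim))
                    cand = cand[hull.find_simplex(cand) >= 0]
                    take = min(n - got, len(cand))
                    upts[got : got + take] = cand[:take]
                    got += take
            else:
                upts = lo + span * rng.random((n, dim))
            # the null must mimic the observed statistic: a mean over the
            # same number of subsample trials
            null[t] = np.mean(
                [
                    _hopkins_once(upts, m, rng, exponent, win, hull, (lo, span), periodic)
                    for _ in range(reps)
                ]
            )
        p_mc = float((np.sum(null >= H) + 1) / (mc_trials + 1))
    return HopkinsResult(variant, H, m, p_beta, p_mc, reps, mc_trials)


def kde_and_qq(values, reference: str = "normal", grid_size: int = 200) -> dict:
    """Plot-ready kernel density and theoretical-vs-empirical quantiles.

    ``reference`` is ``'normal'`` or ``'uniform'``, fitted by moments/range
    to the sample.  Returns a dict with ``grid``, ``density``,
    ``qq_theoretical``, ``qq_empirical``.
    """
    x = np.sort(np.asarray(values, float))
    if len(x) < 20:
        raise ValueError("need at least 20 values")
    if x[0] == x[-1]:
        raise ValueError("degenerate constant sample")
    kde = stats.gaussian_kde(x)
    pad = 0.1 * (x[-1] - x[0])
    grid = np.linspace(x[0] - pad, x[-1] + pad, grid_size)
    probs = (np.arange(1, len(x) + 1) - 0.5) / len(x)
    if reference == "normal":
        theo = stats.norm.ppf(probs, x.mean(), x.std(ddof=1))
    elif reference == "uniform":
        theo = stats.uniform.ppf(probs, x[0], x[-1] - x[0])
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return {
        "grid": grid,
        "density": kde(grid),
        "qq_theoretical": theo,
        "qq_empirical": x,
    }
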