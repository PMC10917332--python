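"""Monte Carlo power analysis for the two-class linear discriminant.

How well can LDA possibly perform when each class contributes only a few
dozen training points?  These experiments draw both classes from the
canonical symmetric setup — centroids (1.2, -1.2) and (-1.2, 1.2), shared
covariance sigma^2·I, so each centroid sits d = 2.4/sqrt(2) ≈ 1.7 from the
ideal boundary y = x — fit LDA on every draw, and record the *training-set*
accuracy (deliberately optimistic: held-out accuracy would be worse).  The
spread of that accuracy across trials quantifies the sample-size penalty;
its 95% band shrinks like a/sqrt(n), and the band's lower bound A_LB is the
quantity a practitioner should compare against an accuracy requirement.

The LDA fit is vectorized across trials (closed-form 2x2 pooled-covariance
inverse), which a unit test pins against the reference single-fit
implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discriminant import pwrong

__all__ = [
    "SeparationSpec",
    "AccuracyCI",
    "ScalingFit",
    "accuracy_experiment",
    "ci_width_scaling",
    "alb_curves",
    "batch_training_accuracy",
]

_CANONICAL_D = 2.4 / math.sqrt(2.0)  # ≈ 1.6971, quoted as 1.7


@dataclass(frozen=True)
class SeparationSpec:
    """Parameters of one accuracy experiment."""

    n_per_class: int = 59
    sigma: float = 1.414
    d: float = _CANONICAL_D
    trials: int = 10_000
    seed: int = 0

    @property
    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        # on the line y = -x, at distance d from the boundary y = x
        c = self.d / math.sqrt(2.0)
        return np.array([c, -c]), np.array([-c, c])


@dataclass
class AccuracyCI:
    median: float
    lo: float
    hi: float
    theoretical: float
    samples: np.ndarray = field(repr=False, default=None)

    @property
    def width(self) -> float:
        return self.hi - self.lo


def batch_training_accuracy(
    n: int,
    sigma: float,
    d: float,
    trials: int,
    rng: np.random.Generator,
    max_chunk_points: int = 4_000_000,
) -> np.ndarray:
    """Training accuracy of LDA over ``trials`` independent draws.

    Vectorized: each chunk draws (B, n, 2) points per class, computes class
    means, the unbiased pooled covariance (divisor 2n - 2), the discriminant
    direction w = S^-1 (m2 - m1), and counts points on their own centroid's
    side of the fitted boundary.  Draws with a singular pooled covariance
    are redrawn (possible only for tiny n).
    """
    mu1 = np.array([d / math.sqrt(2), -d / math.sqrt(2)])
    mu2 = -mu1
    out = np.empty(trials)
    chunk = max(1, min(trials, max_chunk_points // max(n, 1)))
    done = 0
    while done < trials:
        b = min(chunk, trials - done)
        X1 = mu1 + sigma * rng.standard_normal((b, n, 2))
        X2 = mu2 + sigma * rng.standard_normal((b, n, 2))
        m1 = X1.mean(axis=1)
        m2 = X2.mean(axis=1)
        R1 = X1 - m1[:, None, :]
        R2 = X2 - m2[:, None, :]
        S = (
            np.einsum("bni,bnj->bij", R1, R1) + np.einsum("bni,bnj->bij", R2, R2)
        ) / (2 * n - 2)
        det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] * S[:, 1, 0]
        bad = det <= 1e-300
        if np.any(bad):  # redraw degenerate trials next pass
            b_ok = np.flatnonzero(~bad)
        else:
            b_ok = np.arange(b)
        Sinv = np.empty_like(S)
        Sinv[:, 0, 0] = S[:, 1, 1]
        Sinv[:, 1, 1] = S[:, 0, 0]
        Sinv[:, 0, 1] = -S[:, 0, 1]
        Sinv[:, 1, 0] = -S[:, 1, 0]
        Sinv /= np.where(det, det, 1.0)[:, None, None]
        w = np.einsum("bij,bj->bi", Sinv, m2 - m1)
        mid = 0.5 * (m1 + m2)
        s1 = np.einsum("bni,bi->bn", X1 - mid[:, None, :], w)
        s2 = np.einsum("bni,bi->bn", X2 - mid[:, None, :], w)
        acc = ((s1 < 0).sum(axis=1) + (s2 >= 0).sum(axis=1)) / (2 * n)
        take = min(len(b_ok), trials - done)
        out[done : done + take] = acc[b_ok[:take]]
        done += take
    return out


def accuracy_experiment(spec: SeparationSpec) -> AccuracyCI:
    """Distribution of LDA training accuracy under ``spec``.

    Returns the empirical 2.5/50/97.5 percentiles alongside the large-n
    theoretical accuracy 1 - P_wrong(d, sigma).
    """
    if spec.trials < 100:
        raise ValueError("need at least 100 trials")
    rng = np.random.default_rng(spec.seed)
    acc = batch_training_accuracy(
        spec.n_per_class, spec.sigma, spec.d, spec.trials, rng
    )
    lo, med, hi = np.percentile(acc, [2.5, 50, 97.5])
    return AccuracyCI(
        median=float(med),
        lo=float(lo),
        hi=float(hi),
        theoretical=1.0 - pwrong(spec.d, spec.sigma),
        samples=acc,
    )


@dataclass
class ScalingFit:
    """Least-squares fit of CI width = a / sqrt(n) for one sigma."""

    sigma: float
    a: float
    n_grid: np.ndarray
    widths: np.ndarray
    residuals: np.ndarray

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def ci_width_scaling(
    sigma_grid=(0.707, 1.0, 1.414, 2.0, 2.83),
    n_grid=(10, 20, 40, 80, 160, 320, 500),
    trials: int = 2000,
    seed: int = 0,
    d: float = _CANONICAL_D,
) -> list[ScalingFit]:
    """Fit the 1/sqrt(n) law of the accuracy-CI width for each sigma."""
    n_grid = np.asarray(n_grid, int)
    if len(n_grid) < 3:
        raise ValueError("need at least 3 sample sizes to fit the scaling law")
    fits = []
    for si, sigma in enumerate(sigma_grid):
        widths = np.empty(len(n_grid))
        for ni, n in enumerate(n_grid):
            rng = np.random.default_rng((seed, si, ni))
            acc = batch_training_accuracy(int(n), float(sigma), d, trials, rng)
            lo, hi = np.percentile(acc, [2.5, 97.5])
            widths[ni] = hi - lo
        x = 1.0 / np.sqrt(n_grid)
        a = float(np.sum(x * widths) / np.sum(x * x))
        fits.append(ScalingFit(float(sigma), a, n_grid, widths, widths - a * x))
    return fits


def alb_curves(
    d_over_sigma_grid=(0.5, 1.0, 1.5, 2.0, 2.5),
    n_grid=(10, 20, 40, 80, 160, 320, 640, 1280, 2560),
    trials: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Lower bound A_LB of the 95% accuracy band per (d/sigma, n).

    sigma is fixed at 1 and d set to the ratio; only d/sigma matters.
    """
    rows = []
    for ri, ratio in enumerate(d_over_sigma_grid):
        for ni, n in enumerate(n_grid):
            rng = np.random.default_rng((seed, ri, ni))
            acc = batch_training_accuracy(int(n), 1.0, float(ratio), trials, rng)
            rows.append(
                {
                    "d_over_sigma": float(ratio),
                    "n": int(n),
                    "A_LB": float(np.percentile(acc, 2.5)),
                    "median_A": float(np.median(acc)),
                }
            )
    return pd.DataFrame(rows)
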