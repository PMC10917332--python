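"""Resampling machinery: taxon bootstrap of the phylogenetic discriminant,
BCa confidence intervals, and dataset-composition tests.

The bootstrap resamples taxa *with replacement* to the original dataset
size and reruns the discriminant for every tree in the ensemble, so a run
of ``n_trials`` trials with ``trees_per_trial`` trees yields
``n_trials x trees_per_trial`` metric samples.  Confidence intervals use
the bias-corrected and accelerated (BCa) bootstrap: the bias correction
comes from the fraction of bootstrap samples below the point estimate, the
acceleration from the jackknife skewness of the statistic.

Two composition tests probe whether the extinct/extant make-up of a class
could be a representative random sample: a permutation test on the rank
distribution of Cg between extinct and extant taxa (two-sided rank-sum
statistic), and an exact binomial "coin-flip" point probability
C(n, k)/2^n for observing a k / (n-k) split of n taxa under fair sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import ClassPartition, PartitionError, TaxonRecord
from .discriminant import fit_pfda
from .phylo import TreeEnsemble

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "BCaInterval",
    "CompositionTestResult",
    "bootstrap_pfda",
    "bca_interval",
    "jackknife_values",
    "permutation_rank_test",
    "coinflip_point_probability",
    "composition_test",
]


@dataclass(frozen=True)
class BootstrapConfig:
    n_trials: int = 2000
    trees_per_trial: int = 100
    seed: int = 0
    lam: float | None = None  # None: re-optimize Pagel's lambda per tree


@dataclass
class BCaInterval:
    level: float
    lo: float
    hi: float
    bias_correction: float
    acceleration: float
    degenerate: bool = False


@dataclass
class BootstrapResult:
    """Metric and posterior samples from a taxon bootstrap."""

    samples: dict[str, np.ndarray]           # metric -> (n_trials*trees,) values
    p2_samples: dict[str, np.ndarray]        # test taxon -> samples
    intervals: dict[str, BCaInterval]
    point: dict[str, float]                  # statistic on the original data
    skipped_redraws: int = 0

    def median(self, key: str) -> float:
        return float(np.median(self.samples[key]))


def bca_interval(
    samples,
    theta_hat: float | None = None,
    jackknife: np.ndarray | None = None,
    level: float = 0.95,
) -> BCaInterval:
    """BCa interval from a bootstrap sample of a statistic.

    ``theta_hat`` is the statistic on the original data (defaults to the
    bootstrap median); ``jackknife`` holds leave-one-out statistic values
    for the acceleration constant (omit for a = 0, i.e. the
    bias-corrected-only interval).  With no bias and no acceleration the
    interval reduces to the percentile method.
    """
    s = np.sort(np.asarray(samples, float))
    if s.size < 100:
        raise ValueError("need at least 100 bootstrap samples")
    if np.ptp(s) == 0:
        c = float(s[0])
        return BCaInterval(level, c, c, 0.0, 0.0, degenerate=True)
    if theta_hat is None:
        theta_hat = float(np.median(s))
    frac = np.mean(s < theta_hat)
    frac = min(max(frac, 1.0 / (len(s) + 1)), 1 - 1.0 / (len(s) + 1))
    z0 = stats.norm.ppf(frac)
    if jackknife is not None:
        j = np.asarray(jackknife, float)
        d = j.mean() - j
        denom = (np.sum(d**2)) ** 1.5
        a = float(np.sum(d**3) / (6 * denom)) if denom > 0 else 0.0
    else:
        a = 0.0
    alpha = (1 - level) / 2
    out = []
    for za in (stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + za) / (1 - a * (z0 + za))
        out.append(float(np.quantile(s, float(np.clip(stats.norm.cdf(adj), 0, 1)))))
    return BCaInterval(level, out[0], out[1], float(z0), a)


def jackknife_values(records, statistic) -> np.ndarray:
    """Leave-one-out values of ``statistic(records_without_i)``."""
    n = len(records)
    return np.array(
        [statistic([r for j, r in enumerate(records) if j != i]) for i in range(n)]
    )


def _resample_partition(
    part: ClassPartition, rng: np.random.Generator
) -> tuple[ClassPartition | None, list[TaxonRecord]]:
    """One with-replacement resample of the pooled taxa, original size.

    Returns None when a class collapses below 3 records (caller redraws).
    Repeated picks of one taxon get a disambiguating suffix so the
    Dataset/partition invariants still hold.
    """
    pool = part.records
    labels = part.labels
    idx = rng.integers(0, len(pool), size=len(pool))
    seen: dict[str, int] = {}
    c1, c2 = [], []
    from dataclasses import replace as _replace

    for i in idx:
        r = pool[i]
        k = seen.get(r.taxon_id, 0)
        seen[r.taxon_id] = k + 1
        rr = r if k == 0 else _replace(r, taxon_id=f"{r.taxon_id}#bs{k}")
        (c1 if labels[i] == 1 else c2).append(rr)
    if len(c1) < 3 or len(c2) < 3:
        return None, []
    return ClassPartition(c1, c2, part.rule), [pool[i] for i in idx]


_METRIC_KEYS = ("A", "B", "MCC", "P_rand")


def bootstrap_pfda(
    part: ClassPartition,
    ensemble: TreeEnsemble | None,
    config: BootstrapConfig,
    test: list[TaxonRecord] | None = None,
    tree_builder=None,
) -> BootstrapResult:
    """Taxon bootstrap of the phylogenetic discriminant.

    For every trial, taxa are resampled with replacement (trials that
    collapse a class below 3 records are redrawn, counted in
    ``skipped_redraws`` so the sample count stays exact) and the
    discriminant is rerun over ``trees_per_trial`` trees.  When
    ``tree_builder`` is given it is called as ``tree_builder(taxa, seed)``
    and must return a TreeEnsemble for those taxa (used with synthetic
    topologies where the bootstrap duplicates tips); otherwise the supplied
    ensemble's trees are used and must contain every pooled taxon.
    """
    test = list(test or [])
    if ensemble is None and tree_builder is None:
        raise ValueError("supply a tree ensemble or a tree_builder")
    rng = np.random.default_rng(config.seed)
    trees_all = list(ensemble) if ensemble is not None else []
    samples = {k: [] for k in _METRIC_KEYS}
    p2 = {r.taxon_id: [] for r in test}
    skipped = 0
    for _ in range(config.n_trials):
        while True:
            bp, _picked = _resample_partition(part, rng)
            if bp is not None:
                break
            skipped += 1
        if tree_builder is not None:
            ens = tree_builder(
                [r.taxon_id for r in bp.records] + [r.taxon_id for r in test],
                int(rng.integers(0, 2**31 - 1)),
            )
            trees = list(ens)[: config.trees_per_trial]
        else:
            pick = rng.integers(0, len(trees_all), size=config.trees_per_trial)
            trees = [trees_all[i] for i in pick]
            # duplicated bootstrap taxa carry suffixed ids absent from the
            # fixed trees; map them back by resampling without duplicates is
            # not equivalent, so fixed-tree mode requires a builder when
            # duplicates occur
            if any("#bs" in r.taxon_id for r in bp.records):
                raise PartitionError(
                    "bootstrap duplicated taxa but no tree_builder was given; "
                    "supply tree_builder to place duplicate tips"
                )
        summaries, mets = fit_pfda(
            bp, TreeEnsemble(trees, config.seed), test, lam=config.lam
        )
        for m in mets:
            for k in _METRIC_KEYS:
                samples[k].append(getattr(m, k))
        for s in summaries:
            p2[s.taxon_id].extend(s.p2_samples)

    samples = {k: np.asarray(v) for k, v in samples.items()}
    p2 = {k: np.asarray(v) for k, v in p2.items()}

    # point estimates on the original data (median over the base ensemble)
    if tree_builder is not None:
        base_ens = tree_builder(
            [r.taxon_id for r in part.records] + [r.taxon_id for r in test],
            config.seed,
        )
    else:
        base_ens = ensemble
    base_summaries, base_mets = fit_pfda(part, base_ens, test, lam=config.lam)
    point = {
        k: float(np.median([getattr(m, k) for m in base_mets])) for k in _METRIC_KEYS
    }
    for s in base_summaries:
        point[f"P2:{s.taxon_id}"] = s.median_p2

    def _maybe_interval(arr, th):
        return bca_interval(arr, theta_hat=th) if arr.size >= 100 else None

    intervals = {
        k: _maybe_interval(samples[k], point[k]) for k in _METRIC_KEYS
    }
    for t, arr in p2.items():
        intervals[f"P2:{t}"] = _maybe_interval(arr, point[f"P2:{t}"])
    return BootstrapResult(samples, p2, intervals, point, skipped)


def permutation_rank_test(
    values,
    labels,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for equal Cg rank distributions between groups.

    The statistic is the rank sum of the smaller group (Wilcoxon/Mann-
    Whitney type); group labels are permuted and the p-value uses the
    (b + 1)/(n_perm + 1) convention.  Rank-based, hence invariant under any
    monotone transform of the values.
    """
    v = np.asarray(values, float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2 or any((lab == g).sum() == 0 for g in groups):
        raise ValueError("need exactly two non-empty groups")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(v)
    sizes = {g: int((lab == g).sum()) for g in groups}
    gmin = min(groups, key=lambda g: sizes[g])
    m = sizes[gmin]
    obs = ranks[lab == gmin].sum()
    mu = ranks.sum() * m / len(v)
    obs_dev = obs - mu
    # vectorized permutation: random m-subsets via argpartition of noise
    B = int(n_perm)
    count = 0
    chunk = max(1, min(B, 20_000))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        noise = rng.random((b, len(v)))
        part_idx = np.argpartition(noise, m, axis=1)[:, :m]
        sums = ranks[part_idx].sum(axis=1)
        dev = sums - mu
        if alternative == "two-sided":
            count += int(np.sum(np.abs(dev) >= abs(obs_dev) - 1e-12))
        elif alternative == "less":
            count += int(np.sum(dev <= obs_dev + 1e-12))
        elif alternative == "greater":
            count += int(np.sum(dev >= obs_dev - 1e-12))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        done += b
    return (count + 1) / (B + 1)


def coinflip_point_probability(k: int, n: int) -> float:
    """Exact binomial point probability C(n, k)/2^n, in log space.

    The probability that fair coin flips produce exactly k of one kind in n
    trials; symmetric in k <-> n - k, maximal at k = n/2.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    log2p = (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    ) / math.log(2.0) - n
    return float(2.0**log2p)


@dataclass
class CompositionTestResult:
    n_total: int
    n_group1: int
    n_group2: int
    perm_p: float
    perm_trials: int
    coinflip_p: float


def composition_test(
    values, labels, n_perm: int = 100_000, seed: int = 0
) -> CompositionTestResult:
    """Run both composition tests on one class subset.

    ``labels`` distinguish extinct/extant; the permutation test asks
    whether the two groups share a Cg rank distribution, the coin-flip test
    whether the group-size split itself is plausible under fair sampling.
    """
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    n1 = int((lab == groups[0]).sum())
    n2 = int((lab == groups[1]).sum())
    p_perm = permutation_rank_test(values, labels, n_perm=n_perm, seed=seed)
    p_coin = coinflip_point_probability(min(n1, n2), n1 + n2)
    return CompositionTestResult(n1 + n2, n1, n2, p_perm, n_perm, p_coin)
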