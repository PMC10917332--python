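"""Compactness-variation statistics and the spinosaurid sensitivity grid.

Repeat measurements of Cg on the same bone of the same taxon routinely
differ by more than 10% of their mean.  The summary statistic used
throughout is the *relative range*,

    relative range = (max - min) / mean x 100  [%],

computed per taxon/bone entry and aggregated as a median across entries.
Because between-class differences in mean Cg are themselves only ~20-30%
in relative terms, individual variation of this size is material to any
classifier that represents a taxon by a single point — which motivates the
sensitivity grid: systematic alternative (MD, Cg) test points for the
spinosaurid taxa, built from remeasurements and allometric rescaling, whose
posterior P2 is re-evaluated variant by variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ClassPartition, TaxonRecord
from .phylo import TreeEnsemble
from . import refdata

__all__ = [
    "VariationEntry",
    "VariantPoint",
    "RegressionResult",
    "relative_range",
    "relative_range_summary",
    "variation_table",
    "aggregate_median_range",
    "group_summary",
    "ols_allometry",
    "make_variants",
    "evaluate_variants",
]


def relative_range(values) -> float:
    """(max - min) / mean x 100, in percent."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("relative range needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("mean must be positive")
    return float((v.max() - v.min()) / m * 100.0)


def relative_range_summary(lo: float, hi: float, mean: float) -> float:
    """Relative range from published (min, max, mean) summary values."""
    if mean <= 0 or hi < lo:
        raise ValueError("invalid summary")
    return (hi - lo) / mean * 100.0


@dataclass
class VariationEntry:
    """Repeat (MD, Cg) measurements of one bone of one taxon."""

    taxon: str
    bone: str
    measurements: list[tuple[float | None, float]]  # (MD mm or None, Cg)

    @property
    def relative_range(self) -> float:
        return relative_range([cg for _, cg in self.measurements])


def variation_table() -> list[VariationEntry]:
    """The embedded multi-measurement compilation as entries."""
    return [VariationEntry(t, b, m) for t, b, m in refdata.variation_entries()]


def aggregate_median_range(entries) -> float:
    """Median per-entry Cg relative range, in percent."""
    entries = list(entries)
    if not entries:
        raise ValueError("no entries")
    return float(np.median([e.relative_range for e in entries]))


def group_summary(part: ClassPartition) -> dict:
    """Per-class mean Cg and the between-class relative range.

    The between-class figure applies the specimen-level formula to the two
    class means: (high - low) / mean-of-the-two x 100.
    """
    m1 = float(np.mean([r.cg for r in part.class1]))
    m2 = float(np.mean([r.cg for r in part.class2]))
    lo, hi = sorted((m1, m2))
    return {
        "mean_cg_class1": m1,
        "mean_cg_class2": m2,
        "between_class_relative_range": (hi - lo) / ((hi + lo) / 2) * 100.0,
    }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float

    @property
    def x_intercept(self) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("flat regression has no x-intercept")
        return -self.intercept / self.slope


def ols_allometry(points) -> RegressionResult:
    """Ordinary least squares of Cg on linear MD (mm).

    Used for within-genus allometry: a strongly negative slope means the
    genus's compactness would extrapolate toward zero at large body size,
    so its data cannot be scaled up to much larger taxa.
    """
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate: all MD values equal")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass(frozen=True)
class VariantPoint:
    """One sensitivity-grid test point."""

    dataset: str       # 'femur' or 'rib'
    base_taxon: str
    variant_id: str    # e.g. 'Spinosaurus 5'
    md_mm: float
    cg: float


def make_variants() -> list[VariantPoint]:
    """Construct the full published sensitivity grid (24 points)."""
    bases = refdata.spinosaurid_base_points()
    out = []
    for ds, taxon, idx, md_rule, cg_rule in refdata.spinosaurid_variant_rules():
        md0, cg0 = bases[ds][taxon]
        out.append(
            VariantPoint(
                dataset=ds,
                base_taxon=taxon,
                variant_id=f"{taxon} {idx}",
                md_mm=md_rule.apply(md0),
                cg=cg_rule.apply(cg0),
            )
        )
    return out


def evaluate_variants(
    variants,
    part: ClassPartition,
    ensemble: TreeEnsemble,
    config=None,
    tree_builder=None,
    strong_support_bound: float = 0.95,
) -> pd.DataFrame:
    """Bootstrap posterior P2 for each variant test point.

    Each variant is scored as a single test taxon against the training
    partition; rows report the median P2 with its BCa 95% interval and a
    ``strong_support`` flag that is True only when the interval's lower
    bound reaches ``strong_support_bound`` (being 95% confident of at most
    5% classification error).
    """
    from .resampling import BootstrapConfig, bootstrap_pfda

    config = config or BootstrapConfig(n_trials=50, trees_per_trial=10)
    rows = []
    for v in variants:
        rec = TaxonRecord(
            taxon_id=v.variant_id.replace(" ", "_"),
            md_mm=v.md_mm,
            cg=v.cg,
            fly_code="0",
            dive_code="unknown",
            role="test",
        )
        res = bootstrap_pfda(
            part, ensemble, config, test=[rec], tree_builder=tree_builder
        )
        iv = res.intervals[f"P2:{rec.taxon_id}"]
        med = float(np.median(res.p2_samples[rec.taxon_id]))
        rows.append(
            {
                "variant": v.variant_id,
                "dataset": v.dataset,
                "rule": part.rule.mode,
                "median_P2": med,
                "lo": iv.lo,
                "hi": iv.hi,
                "strong_support": iv.lo >= strong_support_bound,
            }
        )
    return pd.DataFrame(rows)
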