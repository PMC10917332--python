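"""Tree covariance, Pagel's-lambda scaling, GLS whitening, tree ensembles.

Under Brownian-motion trait evolution on a rooted tree, the expected
covariance between two tips is the depth of their most recent common
ancestor (the shared root-to-tip path length); the variance of a tip is its
root-to-tip distance.  Pagel's lambda rescales the off-diagonal entries of
that matrix by a factor in [0, 1], interpolating between the full Brownian
structure (lambda = 1) and statistical independence of tips (lambda = 0).

"Whitening" multiplies a trait matrix by the inverse lower Cholesky factor
of the (lambda-scaled) covariance, the standard GLS transformation that
renders Brownian residuals uncorrelated with unit structure.  Any square
root would give an equivalent generalized-least-squares fit; the Cholesky
factor is used because it is triangular and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

__all__ = [
    "PhyloCovariance",
    "TreeEnsemble",
    "read_newick",
    "prune_to",
    "bm_covariance",
    "apply_lambda",
    "whitening_matrix",
    "whiten",
    "bm_loglik",
    "optimize_lambda",
    "random_ensemble",
    "pure_birth_tree",
    "simulate_bm",
]


class TreeError(Exception):
    """Invalid tree input (negative branch lengths, missing taxa, ...)."""


@dataclass
class PhyloCovariance:
    """Tip-by-tip Brownian covariance with a Pagel's-lambda knob."""

    matrix: np.ndarray           # symmetric PSD, shared path lengths
    taxa: list[str]              # tip labels, row/column order
    lam: float = 1.0             # Pagel's lambda already applied to `matrix`

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(taxa), self.lam)


@dataclass
class TreeEnsemble:
    """Trees sharing one topology and tip set, with randomized branch lengths."""

    trees: list[dendropy.Tree]
    seed: int

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def read_newick(source) -> dendropy.Tree:
    """Parse a rooted Newick tree (path, file object, or string)."""
    if hasattr(source, "read"):
        data = source.read()
    else:
        s = str(source)
        data = s if s.lstrip().startswith("(") else open(s).read()
    tree = dendropy.Tree.get(data=data, schema="newick")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise TreeError(f"negative branch length {e.length} in tree")
    return tree


def prune_to(tree: dendropy.Tree, taxa: list[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` retaining only the named tips."""
    labels = {t.taxon.label for t in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise TreeError(f"taxa missing from tree: {missing}")
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(taxa)
    return sub


def bm_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance: C[i, j] = depth of MRCA(i, j).

    ``taxa`` fixes the row order (default: tree's leaf order).  Edges with
    no length count as zero; negative lengths are rejected.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if taxa is None:
        taxa = labels
    # node depths from the root
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        if el < 0:
            raise TreeError(f"negative branch length {el}")
        depth[id(node)] = (depth.get(id(node.parent_node), 0.0) if node.parent_node else 0.0) + (
            el if node.parent_node else 0.0
        )
    leaf_by_label = {lf.taxon.label: lf for lf in leaves}
    missing = [t for t in taxa if t not in leaf_by_label]
    if missing:
        raise TreeError(f"taxa missing from tree: {missing}")
    n = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    C = np.zeros((n, n))
    # postorder: the MRCA of tips under different children of a node is that
    # node, so fill cross-child blocks with the node's depth
    tips_under: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            idx = np.array([pos[lbl]] if lbl in pos else [], dtype=int)
            if idx.size:
                C[idx[0], idx[0]] = depth[id(node)]
        else:
            child_sets = [tips_under.pop(id(c), np.empty(0, int)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia, ib = child_sets[a], child_sets[b]
                    if ia.size and ib.size:
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
            idx = np.concatenate(child_sets) if child_sets else np.empty(0, int)
        tips_under[id(node)] = idx
    return PhyloCovariance(C, list(taxa), 1.0)


def apply_lambda(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariances by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = cov.matrix * lam
    np.fill_diagonal(C, np.diag(cov.matrix))
    return PhyloCovariance(C, list(cov.taxa), cov.lam * lam)


def whitening_matrix(cov: PhyloCovariance) -> np.ndarray:
    """Inverse of the lower Cholesky factor of C, so W C W' = I."""
    try:
        L = np.linalg.cholesky(cov.matrix)
    except np.linalg.LinAlgError as exc:
        raise TreeError(
            "tree covariance is singular (duplicate tips at zero distance or "
            "zero-depth tips); cannot whiten"
        ) from exc
    return solve_triangular(L, np.eye(cov.n), lower=True)


def whiten(X: np.ndarray, cov: PhyloCovariance) -> np.ndarray:
    """GLS-whiten a trait matrix (rows ordered like ``cov.taxa``)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != cov.n:
        raise ValueError(f"X has {X.shape[0]} rows, covariance has {cov.n} taxa")
    return whitening_matrix(cov) @ X


def bm_loglik(X: np.ndarray, cov: PhyloCovariance) -> float:
    """Profile log-likelihood of traits under BM with covariance ``cov``.

    Each column of X is modelled as mu·1 + e, e ~ N(0, s2·C); mu and s2 are
    profiled out per column and the column log-likelihoods summed.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] != cov.n:
        X = X.T
    n = cov.n
    c, low = cho_factor(cov.matrix, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    Ci1 = cho_solve((c, low), ones)
    denom = ones @ Ci1
    total = 0.0
    for col in X.T:
        mu = (Ci1 @ col) / denom
        r = col - mu
        s2 = (r @ cho_solve((c, low), r)) / n
        s2 = max(s2, 1e-300)
        total += -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(total)


def optimize_lambda(
    X: np.ndarray,
    cov: PhyloCovariance,
    grid_step: float = 0.01,
) -> float:
    """Maximum-likelihood Pagel's lambda on [0, 1] for traits ``X``.

    A coarse grid scan locates the basin; a bounded scalar optimization
    refines it.  If the refinement fails the best grid point is returned.
    """
    if cov.n < 10:
        raise ValueError("lambda estimation needs at least 10 tips")

    def nll(lam: float) -> float:
        return -bm_loglik(X, apply_lambda(cov, lam))

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    try:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        if res.success and res.fun <= vals[i] + 1e-9:
            return float(np.clip(res.x, 0.0, 1.0))
    except Exception:
        pass
    return float(grid[i])


def random_ensemble(
    tree: dendropy.Tree,
    n: int = 100,
    seed: int = 0,
    factor_range: tuple[float, float] = (0.5, 1.5),
) -> TreeEnsemble:
    """Randomize branch lengths to emulate stratigraphic/branch-length
    uncertainty: each branch is multiplied by an independent uniform factor.

    Topology and tip set are preserved; the ensemble is reproducible from
    ``seed``.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    lo, hi = factor_range
    if not (0 < lo <= hi):
        raise ValueError("factor_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n):
        t = tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length = float(e.length) * float(rng.uniform(lo, hi))
        trees.append(t)
    return TreeEnsemble(trees, seed)


def pure_birth_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) tree with labelled tips t1..tn.

    Implemented directly (exponential waiting times, uniform lineage choice)
    so trees are reproducible from a numpy seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    # grow as (parent_id, birth_time); finalize at the time of the last split
    class _N:
        __slots__ = ("parent", "t", "children", "label")

        def __init__(self, parent, t):
            self.parent, self.t, self.children, self.label = parent, t, [], None

    root = _N(None, 0.0)
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        for _ in range(2):
            child = _N(node, t)
            node.children.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i, leaf in enumerate(active):
        leaf.label = f"t{i + 1}"

    # children are born at their parent's split; an internal node's edge
    # spans its own birth to its split
    def to_newick2(node) -> str:
        if not node.children:
            return f"{node.label}:{t_end - node.t:.10f}"
        split_time = node.children[0].t
        inner = ",".join(to_newick2(c) for c in node.children)
        if node.parent is None:
            return f"({inner});"
        return f"({inner}):{split_time - node.t:.10f}"

    newick = to_newick2(root)
    return dendropy.Tree.get(data=newick, schema="newick")


def simulate_bm(
    cov: PhyloCovariance,
    n_traits: int = 1,
    rate: float = 1.0,
    seed: int = 0,
    mean: float = 0.0,
) -> np.ndarray:
    """Draw traits from N(mean, rate·C): one column per trait."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(cov.n))
    Z = rng.standard_normal((cov.n, n_traits))
    return mean + np.sqrt(rate) * (L @ Z)
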