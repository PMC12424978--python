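"""Beta-diversity metrics, tree building, ordination, and PERMANOVA.

The four community distances the comparison hinges on are implemented from
scratch: Bray-Curtis (abundance, no phylogeny), Jaccard (presence/absence,
no phylogeny), unweighted UniFrac (phylogenetic presence/absence) and
weighted UniFrac (phylogenetic + abundance; classic non-normalized variant
by default). PCoA uses Gower double-centering; group separation is tested
with an adonis-style single-factor PERMANOVA (pseudo-F, R², permutation p).

Trees over features are built by neighbor joining on pairwise p-distances
and midpoint-rooted; fidelity to any particular published tree is not
claimed — UniFrac behaviour is validated against explicit branch-
enumeration oracles instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .profile import FeatureTable


# ---------------------------------------------------------------------------
# pairwise metrics


def _validate_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero")


def bray_curtis(x, y) -> float:
    """Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(x, y) -> float:
    """1 − |support ∩| / |support ∪|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y)
    px, py = x > 0, y > 0
    union = np.count_nonzero(px | py)
    inter = np.count_nonzero(px & py)
    return 1.0 - inter / union


def _subtree_totals(tree: TreeNode, counts: Mapping[str, float],
                    label: str) -> dict[int, float]:
    present: dict[int, float] = {}
    known = set(counts)
    for tip in tree.tips():
        if tip.name in known:
            known.discard(tip.name)
            present[id(tip)] = float(counts[tip.name])
    leftover = {k for k in known if counts[k] > 0}
    if leftover:
        raise ValueError(f"features missing from tree ({label}): {sorted(leftover)}")
    totals: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        tot = present.get(id(node), 0.0) + sum(totals[id(c)] for c in node.children)
        totals[id(node)] = tot
    return totals


def unifrac(tree: TreeNode, x: Mapping[str, float], y: Mapping[str, float],
            weighted: bool = False, normalized: bool = False) -> float:
    """UniFrac distance between two samples on a shared rooted tree.

    Unweighted: fraction of total covered branch length unique to one
    sample. Weighted: Σ_b l_b·|A_b/A_T − B_b/B_T| (classic variant);
    ``normalized=True`` divides by Σ_b l_b·(A_b/A_T + B_b/B_T).
    """
    ax = _subtree_totals(tree, x, "x")
    ay = _subtree_totals(tree, y, "y")
    at = ax[id(tree)]
    bt = ay[id(tree)]
    if weighted and (at == 0 or bt == 0):
        raise ValueError("weighted UniFrac requires non-empty samples")
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        l = node.length or 0.0
        a, b = ax[id(node)], ay[id(node)]
        if weighted:
            num += l * abs(a / at - b / bt)
            den += l * (a / at + b / bt)
        else:
            pa, pb = a > 0, b > 0
            if pa != pb:
                num += l
            if pa or pb:
                den += l
    if weighted:
        return num / den if normalized else num
    return num / den if den > 0 else 0.0


_METRICS = ("braycurtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


def beta_diversity(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise sample distances for one of the four supported metrics."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    samples = table.sample_ids
    n = len(samples)
    mat = np.zeros((n, n))
    counts = table.counts
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError("UniFrac requires a tree")
        vecs = [counts[s].to_dict() for s in samples]
        for i, j in itertools.combinations(range(n), 2):
            d = unifrac(tree, vecs[i], vecs[j],
                        weighted=(metric == "weighted_unifrac"),
                        normalized=normalized)
            mat[i, j] = mat[j, i] = d
    else:
        fn = bray_curtis if metric == "braycurtis" else jaccard
        arrs = [counts[s].to_numpy() for s in samples]
        for i, j in itertools.combinations(range(n), 2):
            mat[i, j] = mat[j, i] = fn(arrs[i], arrs[j])
    return DistanceMatrix(mat, ids=samples)


# ---------------------------------------------------------------------------
# tree building


def _p_distance(a: str, b: str) -> float:
    if len(a) == len(b):
        xa = np.frombuffer(a.encode(), dtype=np.uint8)
        xb = np.frombuffer(b.encode(), dtype=np.uint8)
        return float(np.count_nonzero(xa != xb)) / len(a)
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


def build_tree(sequences: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining tree over feature sequences, midpoint-rooted.

    Pairwise p-distances (Hamming for equal lengths, global edit distance
    over the longer length otherwise); negative NJ branch lengths clamped
    to zero. Deterministic: ids are processed in lexicographic order.
    """
    ids = sorted(sequences)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate feature ids")
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = _p_distance(sequences[ids[i]], sequences[ids[j]])
    dm = DistanceMatrix(mat, ids=ids)
    if n == 2:
        half = mat[0, 1] / 2
        a = TreeNode(name=ids[0], length=half)
        b = TreeNode(name=ids[1], length=half)
        return TreeNode(children=[a, b])
    tree = nj(dm, neg_as_zero=True)
    tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def canonical_newick(tree: TreeNode) -> str:
    """Newick string with children sorted by smallest descendant leaf name."""
    t = tree.copy()

    def key(node):
        return min(tip.name for tip in node.tips(include_self=True))

    for node in t.traverse(include_self=True):
        if node.children:
            node.children.sort(key=key)
    return str(t).strip()


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples × axes (positive eigenvalues only)
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> PCoAResult:
    """Principal coordinates analysis by Gower double-centering of −½D².

    Coordinates come from the positive eigenvalues (descending); negative
    eigenvalues — a signature of non-Euclidean distances — are reported and
    their axes dropped.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
        ids = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        ids = list(ids) if ids is not None else [f"S{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(1.0, abs(vals).max())
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    cols = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else vals[pos]
    return PCoAResult(pd.DataFrame(coords, index=ids, columns=cols), vals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """adonis-style single-factor PERMANOVA result."""

    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "permutation" or "exhaustive"
    n_samples: int
    n_groups: int

    def summary(self) -> str:
        f = "inf" if math.isinf(self.pseudo_F) else f"{self.pseudo_F:.4f}"
        return (
            "PERMANOVA (single factor)\n"
            f"  samples: {self.n_samples}   groups: {self.n_groups}\n"
            f"  pseudo-F: {f}\n"
            f"  R^2:      {self.r_squared:.6f}\n"
            f"  p-value:  {self.p_value:.6g} ({self.method}, "
            f"{self.n_permutations} permutations)\n"
        )


def _ss_parts(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    within_per_group = 0.5 * np.einsum("ia,ij,ja->a", onehot, d2, onehot)
    ss_within = float((within_per_group / sizes).sum())
    return float(ss_total), ss_within


def _f_from_ssw(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def permanova(
    dist: DistanceMatrix | np.ndarray,
    grouping: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """Distance-based permutational ANOVA for one grouping factor.

    SS_total = Σ_{i<j} d²ᵢⱼ / N; SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g;
    pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)); R² = SS_between/SS_total.
    p is estimated by label permutations preserving group sizes, with the
    +1 correction: p = (1 + #{F* ≥ F}) / (1 + n_permutations). When the
    number of distinct labeled assignments is ≤ 10,000 (and ``exhaustive``
    is not False), all of them are enumerated and p is exact.
    """
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    groups = np.asarray(list(grouping))
    n = d.shape[0]
    if groups.shape[0] != n:
        raise ValueError("grouping length must match the distance matrix")
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sizes = np.bincount(inv).astype(float)
    d2 = d ** 2
    onehot = np.eye(a)[inv]
    ss_total, ss_within = _ss_parts(d2, onehot, sizes)

    if ss_total <= 0:  # all samples identical
        return PermanovaResult(math.nan, 0.0, 1.0, 0, seed, "degenerate", n, a)

    f_obs = _f_from_ssw(ss_total, ss_within, n, a)
    r2 = (ss_total - ss_within) / ss_total

    n_distinct = _distinct_assignments(np.bincount(inv).tolist())
    if exhaustive is None:
        exhaustive = n_distinct <= 10_000

    if exhaustive:
        ge = 0
        total = 0
        for perm in _enumerate_assignments(inv):
            oh = np.eye(a)[perm]
            _, ssw = _ss_parts(d2, oh, sizes)
            f = _f_from_ssw(ss_total, ssw, n, a)
            if f >= f_obs - 1e-12 or (math.isinf(f) and math.isinf(f_obs)):
                ge += 1
            total += 1
        return PermanovaResult(f_obs, r2, ge / total, total, seed, "exhaustive", n, a)

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_oh = np.eye(a)[inv[perm_idx]]               # (P, n, a)
    within = 0.5 * np.einsum("pia,ij,pja->pa", perm_oh, d2, perm_oh)
    ssw_p = (within / sizes).sum(axis=1)
    ss_between_p = ss_total - ssw_p
    with np.errstate(divide="ignore"):
        f_p = (ss_between_p / (a - 1)) / (ssw_p / (n - a))
    f_p[ssw_p <= 1e-12 * max(ss_total, 1.0)] = math.inf
    ge = int(np.count_nonzero(f_p >= f_obs - 1e-12))
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed, "permutation", n, a)


def _enumerate_assignments(inv: np.ndarray):
    """Yield every distinct assignment of labels to positions that preserves
    group sizes (labels are distinguishable; groups of equal size are not
    collapsed)."""
    n = len(inv)
    sizes = np.bincount(inv)

    def rec(remaining: tuple[int, ...], group: int, current: np.ndarray):
        if group == len(sizes) - 1:
            out = current.copy()
            out[list(remaining)] = group
            yield out
            return
        for combo in itertools.combinations(remaining, int(sizes[group])):
            nxt = tuple(i for i in remaining if i not in combo)
            current[list(combo)] = group
            yield from rec(nxt, group + 1, current)

    yield from rec(tuple(range(n)), 0, np.zeros(n, dtype=int))


def permanova_report(results: Mapping[tuple[str, str], PermanovaResult]) -> pd.DataFrame:
    """Tabulate PERMANOVA results keyed by (comparison, metric) in the
    metric-by-comparison layout used for cohort summaries."""
    rows = []
    for (comparison, metric), res in results.items():
        rows.append({"comparison": comparison, "metric": metric,
                     "P": res.p_value, "R2": res.r_squared,
                     "pseudo_F": res.pseudo_F})
    return pd.DataFrame(rows)
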