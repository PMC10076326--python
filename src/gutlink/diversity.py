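"""Microbiome diversity and composition analytics.

Alpha diversity per sample (observed taxa, bias-corrected Chao1,
Shannon entropy), Jensen–Shannon beta diversity with classical PCoA,
UPGMA average-linkage clustering to an ultrametric newick tree, and
unweighted UniFrac on a rooted phylogeny. Germ-free samples carry no
microbiota and must be filtered out before calling these (all-zero
samples raise).

Conventions: Shannon uses natural log by default (base switchable);
Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)); the
Jensen–Shannon divergence uses log base 2 so JSD ∈ [0, 1], and the
default distance is sqrt(JSD), which is a metric.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from gutlink.errors import InputError

__all__ = [
    "DiversityResult",
    "alpha_diversity",
    "alpha_diversity_frame",
    "chao1",
    "shannon",
    "jensen_shannon_divergence",
    "jsd_matrix",
    "pcoa",
    "upgma",
    "unweighted_unifrac",
    "unifrac_matrix",
    "rarefy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityResult:
    sample: str
    observed: int
    chao1: float
    shannon: float


# ---------------------------------------------------------------------------
# alpha diversity


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise InputError("counts must be one-dimensional")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise InputError("counts must be nonnegative integers")
    if c.sum() == 0:
        raise InputError("all-zero sample (germ-free samples must be filtered out)")
    return c


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1)/(2(F2+1))."""
    c = _check_counts(counts)
    s_obs = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy of the relative-abundance profile (nats by default)."""
    c = _check_counts(counts)
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def alpha_diversity(counts, sample: str = "", base: float | None = None) -> DiversityResult:
    c = _check_counts(counts)
    return DiversityResult(
        sample=sample,
        observed=int(np.sum(c > 0)),
        chao1=chao1(c),
        shannon=shannon(c, base=base),
    )


def alpha_diversity_frame(
    abundance: pd.DataFrame, base: float | None = None
) -> pd.DataFrame:
    """Alpha diversity per sample column of a taxa × samples count table."""
    rows = []
    for sample in abundance.columns:
        r = alpha_diversity(abundance[sample].to_numpy(), sample=str(sample), base=base)
        rows.append(
            {
                "sample": r.sample,
                "observed": r.observed,
                "chao1": r.chao1,
                "shannon": r.shannon,
            }
        )
    return pd.DataFrame(rows)


def rarefy(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    c = _check_counts(counts).astype(int)
    total = int(c.sum())
    if depth > total:
        raise InputError(f"depth {depth} exceeds sample total {total}")
    reads = np.repeat(np.arange(c.size), c)
    picked = rng.choice(reads, size=depth, replace=False)
    return np.bincount(picked, minlength=c.size)


# ---------------------------------------------------------------------------
# Jensen–Shannon beta diversity


def _check_profile(p, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise InputError(f"{name} has negative entries")
    total = arr.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise InputError(f"{name} sums to {total}, expected 1 within 1e-6")
    return arr


def jensen_shannon_divergence(p, q) -> float:
    """JSD in bits: ½KL(P‖M) + ½KL(Q‖M), M = (P+Q)/2, log base 2."""
    pa = _check_profile(p, "P")
    qa = _check_profile(q, "Q")
    if pa.size != qa.size:
        raise InputError("profiles differ in length")
    m = 0.5 * (pa + qa)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(pa > 0, pa * np.log2(pa / m), 0.0).sum()
        kl_qm = np.where(qa > 0, qa * np.log2(qa / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def jsd_matrix(profiles: pd.DataFrame, sqrt_distance: bool = True) -> pd.DataFrame:
    """Pairwise Jensen–Shannon distance matrix over profile columns.

    ``profiles`` holds one relative-abundance profile per column. The
    default distance is sqrt(JSD) (a metric); ``sqrt_distance=False``
    returns the raw divergence.
    """
    labels = list(profiles.columns)
    n = len(labels)
    d = np.zeros((n, n))
    cols = [profiles[c].to_numpy(dtype=float) for c in labels]
    for i in range(n):
        for j in range(i + 1, n):
            v = jensen_shannon_divergence(cols[i], cols[j])
            d[i, j] = d[j, i] = math.sqrt(v) if sqrt_distance else v
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# ordination


def pcoa(distance: pd.DataFrame, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical multidimensional scaling (principal coordinates).

    Eigendecomposes the double-centred −½D² matrix; coordinates are
    eigvec·sqrt(eigval) for positive eigenvalues, axes sorted by
    eigenvalue descending. The full eigenvalue spectrum (including any
    negative values, reported with a warning when sizeable) is
    returned alongside.
    """
    d = _check_distance(distance)
    n = d.shape[0]
    if k is None:
        k = n - 1
    if not 1 <= k <= n - 1:
        raise InputError(f"k must be in [1, {n - 1}]")
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = eigval[eigval < 0]
    if neg.size and abs(neg.min()) > 1e-8 * max(eigval.max(), 1e-300):
        log.warning(
            "PCoA: negative eigenvalues present (min %.3g vs max %.3g); "
            "the distance is not fully Euclidean",
            neg.min(),
            eigval.max(),
        )
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigval[axis] > 0:
            coords[:, axis] = eigvec[:, axis] * math.sqrt(eigval[axis])
    frame = pd.DataFrame(
        coords,
        index=distance.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, eigval


def _check_distance(distance: pd.DataFrame) -> np.ndarray:
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise InputError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise InputError("distances must be nonnegative")
    return d


# ---------------------------------------------------------------------------
# UPGMA


def upgma(distance: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) clustering to a rooted ultrametric newick.

    The closest pair merges first; ties break on the lexicographically
    smallest label pair, making the output deterministic. Node heights
    are half the merge distance, so cophenetic distances of the output
    reproduce ultrametric inputs exactly.
    """
    d = _check_distance(distance)
    labels = [str(x) for x in distance.index]
    if len(labels) < 2:
        raise InputError("need at least 2 samples")
    # cluster state: id -> (newick string, size, height, smallest member label)
    active: dict[int, tuple[str, int, float, str]] = {
        i: (lab, 1, 0.0, lab) for i, lab in enumerate(labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(active) > 1:
        best = None
        for (i, j), val in dist.items():
            key_pair = tuple(sorted((active[i][3], active[j][3])))
            cand = (val, key_pair, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        val, _, i, j = best
        ni, nj = active.pop(i), active.pop(j)
        height = val / 2.0
        children = sorted(
            [(ni, height - ni[2]), (nj, height - nj[2])], key=lambda c: c[0][3]
        )
        newick = "(" + ",".join(f"{sub[0]}:{bl:.17g}" for sub, bl in children) + ")"
        size = ni[1] + nj[1]
        member = min(ni[3], nj[3])
        # size-weighted average distances to the new cluster
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(a, b)] = v
        for other in active:
            def _get(a: int, b: int) -> float:
                return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

            v = (ni[1] * _get(i, other) + nj[1] * _get(j, other)) / size
            new_dist[(other, next_id)] = v
        active[next_id] = (newick, size, height, member)
        dist = new_dist
        next_id += 1
    root, _, _, _ = next(iter(active.values()))
    return root + ";"


# ---------------------------------------------------------------------------
# unweighted UniFrac


def _parse_tree(tree: str | TreeNode) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    # convert_underscores=False: taxon ids use underscores literally
    return TreeNode.read(_io.StringIO(tree), convert_underscores=False)


def unweighted_unifrac(
    tree: str | TreeNode, community_a: set[str], community_b: set[str]
) -> float:
    """Fraction of branch length unique to one of two communities.

    A branch lies on community X's paths if any leaf below it is in X;
    the distance is (length on exactly one community's paths) /
    (length on either's). Taxa absent from the tree raise, naming the
    taxon.
    """
    t = _parse_tree(tree)
    tips = {tip.name for tip in t.tips()}
    for taxon in sorted(set(community_a) | set(community_b)):
        if taxon not in tips:
            raise InputError(f"taxon {taxon!r} missing from tree")
    unique = 0.0
    union = 0.0
    for node in t.postorder(include_self=False):
        length = node.length or 0.0
        if length < 0:
            raise InputError("branch lengths must be >= 0")
        below = (
            {node.name} if node.is_tip() else {tip.name for tip in node.tips()}
        )
        in_a = bool(below & community_a)
        in_b = bool(below & community_b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    if union == 0.0:
        return 0.0
    return unique / union


def unifrac_matrix(
    tree: str | TreeNode, presence: dict[str, set[str]]
) -> pd.DataFrame:
    """Pairwise unweighted UniFrac over sample presence sets.

    One postorder pass marks, per branch, which samples' paths use it;
    pairwise distances are then vectorised over the branch table.
    """
    t = _parse_tree(tree)
    tips = {tip.name for tip in t.tips()}
    labels = list(presence)
    for lab in labels:
        for taxon in presence[lab]:
            if taxon not in tips:
                raise InputError(f"taxon {taxon!r} missing from tree")
    lengths = []
    member_rows = []
    below: dict[int, set[str]] = {}
    for node in t.postorder(include_self=False):
        if node.is_tip():
            leaves = {node.name}
        else:
            leaves = set()
            for child in node.children:
                leaves |= below[id(child)]
        below[id(node)] = leaves
        lengths.append(node.length or 0.0)
        member_rows.append([bool(leaves & presence[lab]) for lab in labels])
    lens = np.asarray(lengths)
    member = np.asarray(member_rows, dtype=bool)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = float(lens @ (member[:, i] | member[:, j]))
            uniq = float(lens @ (member[:, i] ^ member[:, j]))
            d[i, j] = d[j, i] = uniq / union if union > 0 else 0.0
    return pd.DataFrame(d, index=labels, columns=labels)
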