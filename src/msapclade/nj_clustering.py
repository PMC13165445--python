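"""Nei-Li distances, neighbor joining, outgroup rooting and locus bootstrap.

Dominant markers (AFLP/MSAP bands) are scored presence/absence, and shared
absence carries no phylogenetic signal: an absent band says nothing about
which mutation removed it.  The appropriate pairwise dissimilarity is
therefore the Nei-Li / Dice band-sharing form

    D = 1 - 2a / (2a + b + c)

with ``a`` the bands present in both samples and ``b``, ``c`` the bands
private to each.  Trees are built by Saitou-Nei neighbor joining, rooted on
a designated outgroup, and internal-branch support is estimated by
resampling loci with replacement.

Trees are ``skbio.TreeNode`` objects throughout; bootstrap percentages are
stored on internal nodes as ``node.support`` and serialized as internal node
labels.
"""

from __future__ import annotations

from io import StringIO
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .band_matrix import MISSING, BandMatrix


class DistanceError(ValueError):
    """No usable loci for a pairwise distance."""


# -- Nei-Li distances ------------------------------------------------------


def nei_li_distance(x: Sequence[int], y: Sequence[int]) -> float:
    """Nei-Li (Dice) dissimilarity between two 0/1 band vectors.

    Loci missing (:data:`MISSING`) in either vector are excluded pairwise.
    Shared absences contribute nothing; two vectors whose usable loci are
    all shared absences are at distance 0 by convention.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DistanceError("band vectors differ in length")
    usable = (x != MISSING) & (y != MISSING)
    if not usable.any():
        raise DistanceError("no loci scored in both samples")
    xs, ys = x[usable], y[usable]
    a = int(((xs == 1) & (ys == 1)).sum())
    b = int(((xs == 1) & (ys == 0)).sum())
    c = int(((xs == 0) & (ys == 1)).sum())
    denom = 2 * a + b + c
    return 0.0 if denom == 0 else 1.0 - 2.0 * a / denom


def distance_matrix(m: BandMatrix) -> DistanceMatrix:
    """All pairwise Nei-Li distances for a band matrix (vectorized)."""
    if m.n_samples < 2:
        raise DistanceError("need at least 2 samples")
    v = m.values
    pres = (v == 1).astype(np.int32)
    scored = (v != MISSING).astype(np.int32)
    joint = scored @ scored.T  # jointly scored locus counts
    if (joint[np.triu_indices(m.n_samples, 1)] == 0).any():
        raise DistanceError("a sample pair shares no scored loci")
    a = pres @ pres.T  # shared presences (joint scoring implied)
    with_i = pres @ scored.T  # a + b: i present where j scored
    denom = with_i + with_i.T  # 2a + b + c
    d = 1.0 - 2.0 * a / np.where(denom > 0, denom, 1)
    d[denom == 0] = 0.0  # only shared absences -> 0 by convention
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(np.clip((d + d.T) / 2.0, 0.0, 1.0), ids=m.sample_ids)


# -- neighbor joining ------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    Ties in the Q criterion break on the lowest (i, j) index pair in the
    current taxon order, so the result is deterministic.  Negative estimated
    branch lengths are clamped to zero with the deficit transferred to the
    sibling branch, the standard correction for slightly non-additive data.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >=3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima: flat argmin on C-ordered array
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = clamp_pair(vi, vj)
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        # replace row i with the new node, drop row j
        d[i, :] = dk
        d[:, i] = dk
        d[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # final unrooted join of three subtrees via the three-point formulas
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    v0 = (d01 + d02 - d12) / 2.0
    v1 = (d01 + d12 - d02) / 2.0
    v2 = (d02 + d12 - d01) / 2.0
    for node, v in zip(nodes, (v0, v1, v2)):
        node.length = float(max(v, 0.0))
    root = TreeNode(children=list(nodes))
    return root


def total_branch_length(t: TreeNode) -> float:
    """Sum of all branch lengths in the tree."""
    return float(sum(n.length or 0.0 for n in t.traverse() if not n.is_root()))


# -- rooting ---------------------------------------------------------------


def root_with_outgroup(t: TreeNode, outgroup: str) -> TreeNode:
    """Root a tree on the branch subtending ``outgroup``.

    The outgroup's pendant branch is bisected, so all leaf-to-leaf path
    lengths are preserved.  Idempotent: re-rooting a rooted tree on the same
    leaf returns an equivalent tree.
    """
    if outgroup not in {tip.name for tip in t.tips()}:
        raise KeyError(f"outgroup {outgroup!r} is not a leaf of the tree")
    return t.root_by_outgroup([outgroup])


# -- bootstrap -------------------------------------------------------------


def _bipartitions(t: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, canonicalized.

    Each internal edge splits the taxa in two; the side not containing the
    lexicographically smallest taxon represents the split, which makes the
    encoding invariant to where the tree object happens to be rooted.
    """
    taxa = frozenset(tip.name for tip in t.tips())
    ref = min(taxa)
    out: set[frozenset[str]] = set()
    for node in t.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def bootstrap_supports(
    m: BandMatrix, n_reps: int = 1000, seed: int | None = None
) -> TreeNode:
    """NJ tree from the full matrix with locus-bootstrap branch supports.

    Loci are resampled with replacement to the original count; each
    replicate matrix is run through the same distance + NJ pipeline, and
    each internal branch of the full-data tree is annotated with the
    percentage of replicates containing its bipartition (``node.support``).
    Deterministic for a given seed.  The matrix should already be
    monomorphic-filtered, mirroring the analysis pipeline.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(distance_matrix(m))
    taxa = frozenset(m.sample_ids)
    ref = min(taxa)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, m.n_loci, size=m.n_loci)
        rep = BandMatrix(
            sample_ids=list(m.sample_ids),
            locus_ids=[f"L{k}" for k in range(m.n_loci)],
            values=m.values[:, idx],
            marker_system=m.marker_system,
        )
        for split in _bipartitions(neighbor_joining(distance_matrix(rep))):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            node.support = 100.0 * counts.get(side, 0) / n_reps
    return tree


def support_for_clade(t: TreeNode, clade: Iterable[str]) -> float | None:
    """Bootstrap percentage attached to the branch splitting off ``clade``.

    ``None`` if no internal branch of the tree induces that bipartition.
    """
    taxa = frozenset(tip.name for tip in t.tips())
    ref = min(taxa)
    want = frozenset(clade)
    if ref in want:
        want = taxa - want
    for node in t.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = taxa - side
        if side == want and hasattr(node, "support"):
            return float(node.support)
    return None


# -- serialization ---------------------------------------------------------


def to_newick(t: TreeNode, decimals: int = 5) -> str:
    """Newick string with fixed-precision branch lengths.

    Internal nodes annotated with ``support`` are labeled with the support
    percentage (one decimal).
    """

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            sup = getattr(node, "support", None)
            label = f"({inner})" + (f"{sup:.1f}" if sup is not None else node.name or "")
        if node.length is None or node.is_root():
            return label
        return f"{label}:{node.length:.{decimals}f}"

    return fmt(t) + ";"


def read_newick(source: str) -> TreeNode:
    """Read a newick tree from a path or literal string."""
    if source.strip().endswith(";"):
        return TreeNode.read(StringIO(source))
    return TreeNode.read(source)
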