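"""Distance matrices, UPGMA dendrograms and bootstrap support for band data.

The character unit is the dominant allele band (a (locus, size) column of
the 0/1 matrix).  Pairwise distances use the coefficients standard for
dominant marker data — Dice (default), Jaccard and simple matching — with
pairwise deletion of columns where either accession's locus call is
missing.  Trees are built by UPGMA (size-weighted average linkage), which
yields an ultrametric, rooted dendrogram; clade support is estimated by
bootstrap resampling of band columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AlleleMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "pairwise_distance",
    "upgma",
    "bootstrap_support",
    "write_newick",
    "to_newick",
]

METRICS = ("dice", "jaccard", "simple_matching")


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal
    metric: str = "dice"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def pairwise_distance(matrix: AlleleMatrix, metric: str = "dice") -> DistanceMatrix:
    """Pairwise dissimilarity between accessions on the binary band matrix.

    With per-pair band counts a (shared presence), b, c (mismatches) and
    d (shared absence) over the columns both accessions were scored for:

    * dice:            1 - 2a / (2a + b + c)
    * jaccard:         1 - a / (a + b + c)
    * simple_matching: (b + c) / (a + b + c + d)

    Columns where either accession's locus is missing are deleted pairwise.
    Two accessions with no band present among comparable columns count as
    identical (distance 0) under dice/jaccard.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    vals = matrix.values
    n = len(matrix.accession_ids)
    if n < 2:
        raise ValueError("need at least two accessions")
    out = np.zeros((n, n), dtype=float)
    present = vals == 1
    absent = vals == 0
    scored = vals >= 0
    for i in range(n):
        for j in range(i + 1, n):
            comparable = scored[i] & scored[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"accessions {matrix.accession_ids[i]!r} and "
                    f"{matrix.accession_ids[j]!r} share no comparable columns"
                )
            a = int((present[i] & present[j] & comparable).sum())
            b = int((present[i] & absent[j] & comparable).sum())
            c = int((absent[i] & present[j] & comparable).sum())
            if metric == "dice":
                denom = 2 * a + b + c
                d_ij = 1.0 - 2.0 * a / denom if denom else 0.0
            elif metric == "jaccard":
                denom = a + b + c
                d_ij = 1.0 - a / denom if denom else 0.0
            else:
                d_ij = (b + c) / m
            out[i, j] = out[j, i] = d_ij
    return DistanceMatrix(ids=matrix.accession_ids, values=out, metric=metric)


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry labels, internal nodes heights/support."""

    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        return tuple(l for child in self.children for l in child.leaves())


@dataclass
class UltrametricTree:
    """UPGMA dendrogram: rooted, binary, all leaves equidistant from root."""

    root: TreeNode
    ids: tuple[str, ...]
    cophenetic: np.ndarray  # pairwise merge distances, order = ids
    metric: str = "dice"

    @property
    def height(self) -> float:
        return self.root.height

    def cophenetic_distance(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.cophenetic[i, j])

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes except the root (the split units)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode, is_root: bool) -> None:
            if node.is_leaf:
                return
            if not is_root:
                out.add(frozenset(node.leaves()))
            for child in node.children:
                walk(child, False)

        walk(self.root, True)
        return out

    def supports(self) -> dict[frozenset[str], float]:
        out: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.support is not None:
                out[frozenset(node.leaves())] = node.support
            for child in node.children:
                walk(child)

        walk(self.root)
        return out


def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """Size-weighted average-linkage (UPGMA) clustering of a distance matrix.

    At each step the closest cluster pair merges at node height d/2; the
    new cluster's distance to any other is the size-weighted mean of the
    merged members' distances (equivalently the mean over all leaf pairs).
    Ties are broken by the lexicographically smallest pair of minimal leaf
    labels, making the topology reproducible bit-for-bit.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two accessions")
    dist = dm.values.copy()
    active = list(range(n))
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=dm.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    min_label = {i: dm.ids[i] for i in range(n)}
    coph = np.zeros((n, n), dtype=float)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    ext = {i: i for i in range(n)}  # cluster id -> row index in dist

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                ci, cj = active[ai], active[aj]
                d = dist[ext[ci], ext[cj]]
                la, lb = sorted((min_label[ci], min_label[cj]))
                key = (d, la, lb)
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        _, ci, cj = best
        d_min = best[0][0]
        node = TreeNode(
            height=d_min / 2.0,
            children=tuple(
                sorted((nodes[ci], nodes[cj]), key=lambda nd: min(nd.leaves()))
            ),
        )
        for li in members[ci]:
            for lj in members[cj]:
                coph[li, lj] = coph[lj, li] = d_min
        # weighted average update against every other active cluster
        row_i, row_j = ext[ci], ext[cj]
        ni, nj = sizes[ci], sizes[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            rk = ext[ck]
            dist[row_i, rk] = dist[rk, row_i] = (
                ni * dist[row_i, rk] + nj * dist[row_j, rk]
            ) / (ni + nj)
        new_id = next_id
        next_id += 1
        nodes[new_id] = node
        sizes[new_id] = ni + nj
        min_label[new_id] = min(min_label[ci], min_label[cj])
        members[new_id] = members[ci] + members[cj]
        ext[new_id] = row_i
        active = [c for c in active if c not in (ci, cj)] + [new_id]

    return UltrametricTree(
        root=nodes[active[0]], ids=dm.ids, cophenetic=coph, metric=dm.metric
    )


def bootstrap_support(
    matrix: AlleleMatrix,
    metric: str = "dice",
    replicates: int = 1000,
    seed: int = 0,
    by_locus: bool = False,
) -> UltrametricTree:
    """UPGMA tree with clade bootstrap support from column resampling.

    Bands (columns of the 0/1 matrix) are resampled with replacement
    ``replicates`` times; the support of each clade of the reference tree
    is the percentage of replicate trees containing the same leaf set.
    ``by_locus=True`` resamples whole loci (column blocks) instead of
    single bands.  Fixed ``seed`` gives bit-identical supports.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reference = upgma(pairwise_distance(matrix, metric))
    counts: dict[frozenset[str], int] = {clade: 0 for clade in reference.clades()}

    n_cols = len(matrix.columns)
    if by_locus:
        loci = []
        blocks: dict[str, list[int]] = {}
        for j, (locus, _) in enumerate(matrix.columns):
            if locus not in blocks:
                loci.append(locus)
                blocks[locus] = []
            blocks[locus].append(j)
    for _ in range(replicates):
        if by_locus:
            picked_loci = rng.choice(len(loci), size=len(loci), replace=True)
            cols = np.concatenate([blocks[loci[k]] for k in picked_loci])
        else:
            cols = rng.integers(0, n_cols, size=n_cols)
        sub = AlleleMatrix(
            accession_ids=matrix.accession_ids,
            columns=tuple(matrix.columns[j] for j in cols),
            values=matrix.values[:, cols],
            groups=matrix.groups,
        )
        rep_tree = upgma(pairwise_distance(sub, metric))
        rep_clades = rep_tree.clades()
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1

    def attach(node: TreeNode, is_root: bool) -> None:
        if node.is_leaf:
            return
        if not is_root:
            node.support = 100.0 * counts[frozenset(node.leaves())] / replicates
        for child in node.children:
            attach(child, False)

    attach(reference.root, True)
    return reference


_NEWICK_META = set("(),:;'\"[] \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(
    tree: UltrametricTree, min_support: float | None = None, decimals: int = 6
) -> str:
    """Serialize as Newick with branch lengths and internal support labels.

    Supports below ``min_support`` (e.g. the conventional 30% display
    cutoff) are omitted from the rendered labels but remain on the tree
    object.
    """

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.label)}:{length:.{decimals}f}"
        inner = ",".join(render(c, node.height) for c in node.children)
        label = ""
        if node.support is not None and (
            min_support is None or node.support >= min_support
        ):
            label = f"{node.support:g}"
        return f"({inner}){label}:{length:.{decimals}f}"

    root = tree.root
    inner = ",".join(render(c, root.height) for c in root.children)
    label = ""
    if root.support is not None:
        label = f"{root.support:g}"
    return f"({inner}){label};"


def write_newick(
    tree: UltrametricTree, path, min_support: float | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, min_support=min_support) + "\n")
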