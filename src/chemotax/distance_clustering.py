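"""Simple-matching similarity, genetic distances and UPGMA dendrograms.

The similarity between two binary band profiles is the simple matching
coefficient Ssm = (1-1 matches + 0-0 matches) / (band columns); the genetic
distance is d = 1 - Ssm, so both live in [0, 1].  UPGMA (unweighted
pair-group method with arithmetic mean) agglomerates the two clusters at
minimal average distance, placing the merge node at half that distance, which
yields an ultrametric tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "TreeNode",
    "simple_matching_matrix",
    "genetic_distance_matrix",
    "upgma",
    "cophenetic",
    "to_newick",
    "read_newick",
    "read_phylip_distances",
    "write_phylip_distances",
]


@dataclass(frozen=True)
class _LabeledSquare:
    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    _diag: ClassVar[float] = 0.0

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.ids)
        values = np.asarray(self.values, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("duplicate sample ids")
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(values), self._diag, atol=1e-12):
            raise ValueError(f"diagonal must equal {self._diag}")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class SimilarityMatrix(_LabeledSquare):
    """Square symmetric matrix of Ssm values with unit diagonal."""

    _diag = 1.0


@dataclass(frozen=True)
class DistanceMatrix(_LabeledSquare):
    """Square symmetric matrix of genetic distances with zero diagonal."""

    _diag = 0.0


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric dendrogram; leaves have height 0."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree over the clustered samples."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names
        if len(names) < 2:
            raise ValueError("dendrogram needs at least 2 leaves")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        self._check(self.root)

    @staticmethod
    def _check(node: TreeNode) -> None:
        if node.height < -1e-12:
            raise ValueError("negative node height")
        if node.is_leaf:
            if node.name is None:
                raise ValueError("leaf without a name")
            if abs(node.height) > 1e-12:
                raise ValueError("leaf height must be 0")
        for c in node.children:
            if c.height > node.height + 1e-9:
                raise ValueError("child height exceeds parent height")
            Dendrogram._check(c)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())  # type: ignore[misc]

    @property
    def height(self) -> float:
        return self.root.height


def simple_matching_matrix(m) -> SimilarityMatrix:
    """Simple matching coefficient between every pair of samples.

    ``Ssm(i, j)`` is the fraction of band columns at which samples i and j
    agree (both present or both absent).  Computed as 1 minus the Hamming
    fraction.
    """
    if m.n_bands == 0:
        raise ValueError("band matrix has no band columns")
    x = m.presence.astype(bool)
    ssm = 1.0 - squareform(pdist(x, metric="hamming"))
    np.fill_diagonal(ssm, 1.0)
    return SimilarityMatrix(m.samples, ssm)


def genetic_distance_matrix(s: SimilarityMatrix) -> DistanceMatrix:
    """Genetic distance d = 1 - Ssm, elementwise."""
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(s.ids, d)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Repeatedly merges the pair of clusters at minimal distance; the merge node
    sits at half that distance and the new cluster's distance to any other is
    the size-weighted arithmetic mean ``(|A| d(A,C) + |B| d(B,C)) / (|A|+|B|)``
    — equivalent to averaging all member pairwise distances of the original
    matrix.  Ties are broken toward the smallest (row, column) index pair in
    the current cluster order, making the output deterministic.
    """
    work = d.values.astype(float).copy()
    if (work < 0).any():
        raise ValueError("negative distances")
    nodes: list[TreeNode] = [TreeNode(0.0, name=s) for s in d.ids]
    sizes: list[int] = [1] * d.n
    first_leaf: list[int] = list(range(d.n))  # original index, for child ordering
    while len(nodes) > 1:
        n = len(nodes)
        best: tuple[int, int] | None = None
        best_d = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if work[i, j] < best_d:
                    best_d = work[i, j]
                    best = (i, j)
        assert best is not None
        i, j = best
        children = (nodes[i], nodes[j])
        if first_leaf[j] < first_leaf[i]:
            children = (nodes[j], nodes[i])
        merged = TreeNode(best_d / 2.0, children=children)
        wi, wj = sizes[i], sizes[j]
        new_row = (wi * work[i, :] + wj * work[j, :]) / (wi + wj)
        keep = [k for k in range(n) if k not in (i, j)]
        work = np.pad(work[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        work[-1, :-1] = work[:-1, -1] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [wi + wj]
        first_leaf = [first_leaf[k] for k in keep] + [min(first_leaf[i], first_leaf[j])]
    return Dendrogram(nodes[0])


def cophenetic(t: Dendrogram) -> DistanceMatrix:
    """Tree-induced distances: 2 x height of each pair's lowest common ancestor."""
    names = t.leaf_names
    index = {s: k for k, s in enumerate(names)}
    d = np.zeros((len(names), len(names)))

    def visit(node: TreeNode) -> list[int]:
        if node.is_leaf:
            return [index[node.name]]  # type: ignore[index]
        groups = [visit(c) for c in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for u in groups[a]:
                    for v in groups[b]:
                        d[u, v] = d[v, u] = 2.0 * node.height
        return [u for g in groups for u in g]

    visit(t.root)
    return DistanceMatrix(names, d)


def to_newick(t: Dendrogram, precision: int = 6) -> str:
    """Serialize to Newick; branch length = parent height - child height."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}"

    def render(node: TreeNode, parent_height: float) -> str:
        length = fmt(parent_height - node.height)
        if node.is_leaf:
            return f"{node.name}:{length}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length}"

    root = t.root
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def read_newick(text: str) -> Dendrogram:
    """Parse a Newick string into a :class:`Dendrogram`.

    Node heights are reconstructed from root-to-node path lengths; the input
    must be ultrametric (all leaves equidistant from the root) within a small
    tolerance.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    depths: dict[object, float] = {}

    def depth_of(node) -> float:
        if node.parent_node is None:
            return 0.0
        return depths[node.parent_node] + (node.edge.length or 0.0)

    for node in tree.preorder_node_iter():
        depths[node] = depth_of(node)
    leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    total = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > 1e-6 * max(total, 1.0):
        raise ValueError("tree is not ultrametric")

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(0.0, name=node.taxon.label.replace(" ", "_"))
        return TreeNode(
            max(total - depths[node], 0.0),
            children=tuple(convert(c) for c in node.child_nodes()),
        )

    return Dendrogram(convert(tree.seed_node))


def write_phylip_distances(d: DistanceMatrix, path: str | Path, decimals: int = 6) -> None:
    """Write a PHYLIP square distance matrix (count line, then label + row)."""
    lines = [f"{d.n}"]
    for s, row in zip(d.ids, d.values):
        lines.append(s + "  " + "  ".join(f"{v:.{decimals}f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix."""
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty distance file")
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"{path}: row {parts[0]!r} has {len(parts) - 1} values, expected {n}")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(tuple(ids), np.array(rows))
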