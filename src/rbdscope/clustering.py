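"""Position-specific domain clustering: p-distances, neighbor joining, purity.

Individual domains excised from many proteins, aligned together, can be
compared by p-distance (one minus fractional identity over mutually
non-gap columns). Neighbor joining on that matrix yields a dendrogram; if
each domain position in the protein (first domain, second domain, ...)
forms its own cluster, the domains are conserved position-specifically.
The nearest-neighbour purity score quantifies that: the fraction of leaves
whose closest leaf in the matrix belongs to the same position class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Msa, ValidationError
from .redundancy import pairwise_identity

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric distances between labelled domains.

    Each leaf is a (species_tag, position_index) pair; its display name is
    the concatenation, e.g. ``("hs", 3)`` -> ``"hs3"``.
    """

    labels: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distances must be finite")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        names = self.names
        if len(set(names)) != len(names):
            raise ValidationError("leaf names must be unique")

    @property
    def names(self) -> list[str]:
        return [f"{sp}{pos}" for sp, pos in self.labels]

    @property
    def n(self) -> int:
        return len(self.labels)


def domain_distance_matrix(msa: Msa, labels: list[tuple[str, int]]) -> DistanceMatrix:
    """p-distance matrix between aligned domain sequences.

    ``labels`` pairs each alignment row with its (species_tag,
    position_index). A pair with no mutually non-gap column gets the
    maximal distance 1.0 with a warning.
    """
    if len(labels) != len(msa):
        raise ValidationError("one (species, position) label required per sequence")
    n = len(msa)
    values = np.zeros((n, n))
    rows = [r.residues for r in msa.records]
    for i in range(n):
        for j in range(i + 1, n):
            overlap = any(
                a != "-" and b != "-" for a, b in zip(rows[i], rows[j])
            )
            if not overlap:
                warnings.warn(
                    f"sequences {msa.records[i].id!r} and {msa.records[j].id!r} "
                    "share no mutually non-gap column; distance set to 1.0",
                    stacklevel=2,
                )
                d = 1.0
            else:
                d = 1.0 - pairwise_identity(rows[i], rows[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


@dataclass
class TreeNode:
    name: str | None = None  # leaf name; internal nodes are unnamed
    length: float = 0.0  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree rendered with an arbitrary internal node as root."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                names.append(node.name)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return names

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(render(ch) for ch in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(render(ch) for ch in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else None,
                length=dnode.edge.length or 0.0,
            )
            node.children = [convert(ch) for ch in dnode.child_nodes()]
            return node

        return cls(root=convert(dtree.seed_node))

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every unordered pair of leaves."""
        distances: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            below: dict[str, float] = {}
            child_maps = [walk(ch) for ch in node.children]
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, da in child_maps[a].items():
                        for lb, db in child_maps[b].items():
                            key = tuple(sorted((la, lb)))
                            distances[key] = da + db
            for cm in child_maps:
                for leaf, d in cm.items():
                    below[leaf] = d + node.length
            return below

        walk(self.root)
        return distances


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest
    (name, name) pair. Negative branch-length estimates are clamped to
    zero (logged). Additive matrices are reproduced exactly.
    """
    if matrix.n < 3:
        raise ValidationError("neighbor joining needs at least 3 leaves")

    D: dict[str, dict[str, float]] = {}
    nodes: dict[str, TreeNode] = {}
    names = matrix.names
    for i, a in enumerate(names):
        nodes[a] = TreeNode(name=a)
        D[a] = {b: float(matrix.values[i, j]) for j, b in enumerate(names) if j != i}
    active = sorted(names)
    counter = 0

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.info("negative NJ branch length %.4g at %s clamped to 0", length, context)
            return 0.0
        return length

    while len(active) > 2:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best_pair = None
        best_q = np.inf
        for ai in range(n):
            for bi in range(ai + 1, n):
                a, b = active[ai], active[bi]
                q = (n - 2) * D[a][b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = D[a][b] - la
        nodes[a].length = clamp(la, f"join({a},{b})")
        nodes[b].length = clamp(lb, f"join({a},{b})")
        counter += 1
        new = f"\x00inner{counter}"  # cannot collide with user leaf names
        nodes[new] = TreeNode(children=[nodes[a], nodes[b]])
        D[new] = {}
        for k in active:
            if k in (a, b):
                continue
            d = 0.5 * (D[a][k] + D[b][k] - D[a][b])
            D[new][k] = d
            D[k][new] = d
        active = sorted(k for k in active if k not in (a, b))
        active.append(new)
        active.sort()

    a, b = active
    edge = clamp(D[a][b], f"final({a},{b})")
    if not nodes[a].is_leaf:
        root, other = nodes[a], nodes[b]
    else:
        root, other = nodes[b], nodes[a]
    other.length = edge
    root.children.append(other)
    root.length = 0.0
    return Tree(root=root)


def position_cluster_purity(
    matrix: DistanceMatrix,
) -> float:
    """Nearest-neighbour purity of position classes in a distance matrix.

    For every leaf whose position class has at least one other member, find
    its nearest neighbour (smallest distance; ties by smallest leaf name)
    and score a hit when the neighbour shares the position class. Leaves in
    singleton classes are excluded with a warning. 1.0 means perfectly
    position-specific clustering.
    """
    positions = [pos for _, pos in matrix.labels]
    class_sizes: dict[int, int] = {}
    for pos in positions:
        class_sizes[pos] = class_sizes.get(pos, 0) + 1
    if len(class_sizes) < 2:
        raise ValidationError("need at least 2 position classes")
    names = matrix.names
    eligible = [i for i, pos in enumerate(positions) if class_sizes[pos] >= 2]
    skipped = matrix.n - len(eligible)
    if skipped:
        warnings.warn(
            f"{skipped} leaves in singleton position classes excluded from purity",
            stacklevel=2,
        )
    if not eligible:
        raise ValidationError("no position class has more than one member")
    hits = 0
    for i in eligible:
        order = sorted(
            (j for j in range(matrix.n) if j != i),
            key=lambda j: (matrix.values[i, j], names[j]),
        )
        nearest = order[0]
        if positions[nearest] == positions[i]:
            hits += 1
    return hits / len(eligible)
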