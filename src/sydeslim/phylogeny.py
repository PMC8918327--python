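"""Distance-based protein phylogeny: Kimura-corrected distances,
neighbor joining, column bootstrap, Newick output.

This is a deliberate distance/NJ surrogate for a maximum-likelihood
protein tree: distances are Kimura-corrected p-distances
(``d = -ln(1 - p - 0.2 p^2)``), trees are built by standard neighbor
joining with a deterministic lexicographic tie-break, and internal-branch
supports come from resampling alignment columns with replacement.
NJ is exact on additive distance matrices, which is the property the test
suite leans on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import GAP, MultipleAlignment

#: distances are capped here when p-distance saturates (1 - p - 0.2 p^2 <= 0)
MAX_DISTANCE = 10.0


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite and non-negative")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in self.matrix[i]) + "\n")


def protein_distance(gapped_a: str, gapped_b: str) -> float:
    """Kimura-corrected distance between two aligned protein sequences.

    Columns with a gap in either sequence are ignored.  Saturated
    p-distances (p such that 1 - p - 0.2 p^2 <= 0, i.e. p >= ~0.85) are
    capped at :data:`MAX_DISTANCE` with a warning.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings differ in length")
    shared = mismatch = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x != y:
            mismatch += 1
    if shared == 0:
        raise ValueError("no shared ungapped columns")
    p = mismatch / shared
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        warnings.warn(f"saturated distance (p={p:.3f}); capped at {MAX_DISTANCE}",
                      stacklevel=2)
        return MAX_DISTANCE
    return min(-math.log(arg), MAX_DISTANCE)


def distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    labels = tuple(msa.rows)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = protein_distance(msa.rows[labels[i]], msa.rows[labels[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration; ties broken by lexicographic label pair.

    Fewer than 3 taxa yield a degenerate tree: a single leaf, or two
    leaves joined by one edge carrying the full distance split evenly.
    """
    labels = list(dm.labels)
    n = len(labels)
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    if n == 1:
        return nodes[labels[0]]
    if n == 2:
        root = TreeNode()
        half = dm.matrix[0, 1] / 2.0
        root.children = [(nodes[labels[0]], half), (nodes[labels[1]], half)]
        return root

    d: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                d[(labels[i], labels[j])] = float(dm.matrix[i, j])
    active = sorted(labels)

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    while len(active) > 3:
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        m = len(active)
        best = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and best is not None
                                          and (a, b) < best):
                    best_q = q
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)  # negative NJ estimates clamped
        new_name = f"({a},{b})"
        node = TreeNode(name="")
        node.children = [(nodes[a], la), (nodes[b], lb)]
        nodes[new_name] = node
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new_name, c)] = d[(c, new_name)] = max(dn, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_name])

    # join the last three nodes on an unrooted star
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root.children = [
        (nodes[a], max(la, 0.0)),
        (nodes[b], max(lb, 0.0)),
        (nodes[c], max(lc, 0.0)),
    ]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (leaf sets of internal edges)."""
    all_leaves = frozenset(tree.leaves())
    parts: set[frozenset[str]] = set()

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(ch) for ch, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            # canonicalize: store the side not containing the first leaf
            other = all_leaves - below
            parts.add(below if min(below) > min(other) else other)
        return below

    for child, _ in tree.children:
        visit(child)
    return parts


def resample_columns(msa: MultipleAlignment, rng: np.random.Generator) -> MultipleAlignment:
    cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
    return MultipleAlignment(
        {sid: "".join(gapped[c] for c in cols) for sid, gapped in msa.rows.items()}
    )


def bootstrap_supports(
    msa: MultipleAlignment, n_replicates: int = 500, seed: int = 0
) -> TreeNode:
    """NJ tree from the full alignment with column-bootstrap supports.

    Supports are percentages of replicates whose NJ tree contains each
    internal bipartition of the full-data tree.  Replicate r uses the
    child stream ``seed + r`` of a fixed protocol, so supports do not
    depend on taxa order.
    """
    full = neighbor_joining(distance_matrix(msa))
    target = {part: 0 for part in bipartitions(full)}
    for r in range(n_replicates):
        rng = np.random.default_rng((seed, r))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = neighbor_joining(distance_matrix(resample_columns(msa, rng)))
        rep_parts = bipartitions(rep)
        for part in target:
            if part in rep_parts:
                target[part] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(ch, all_leaves) for ch, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = below if min(below) > min(other) else other
            node.support = 100.0 * target[key] / n_replicates
        return below

    leaves = frozenset(full.leaves())
    for child, _ in full.children:
        annotate(child, leaves)
    return full


_NEWICK_META = set("(),:;'[] \t\n")


def _quote(label: str) -> str:
    if not label:
        return label
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    """Newick text with branch lengths and bootstrap supports as internal labels."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name)
        inner = ",".join(
            f"{render(ch)}:{length:.6g}" for ch, length in node.children
        )
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}"

    return render(tree) + ";"
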