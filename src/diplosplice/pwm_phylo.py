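"""PWM-based clustering of species splice sites.

Per-species, per-class (canonical / noncanonical) PWMs are built from
phylo-mode splice-site windows with the conserved terminal dinucleotide
columns removed (so the invariant GT/AG does not mask the informative
positions). A pairwise distance matrix over the PWMs (Frobenius norm by
default) is clustered with UPGMA into an ultrametric rooted tree, written
as newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .splice_sites import (
    ACCEPTOR_LAYOUT,
    DONOR_LAYOUT,
    PWM,
    build_pwm,
)

__all__ = [
    "SpliceSiteClassPWM",
    "DistanceMatrix",
    "TreeNode",
    "ClusterTree",
    "strip_terminal_dinucs",
    "pwm_distance",
    "distance_matrix",
    "upgma",
    "splice_site_tree",
]

SITES = ("5ss", "3ss")
#: expected phylo-mode window lengths before stripping
_PHYLO_LEN = {"5ss": sum(DONOR_LAYOUT["phylo"]), "3ss": sum(ACCEPTOR_LAYOUT)}
#: column count after removing the terminal dinucleotide
_STRIPPED_LEN = {"5ss": 10, "3ss": 21}


def strip_terminal_dinucs(windows: Sequence[str], site: str) -> List[str]:
    """Remove the conserved intron-terminal dinucleotide columns.

    5'ss windows (3 exonic + 9 intronic nt) lose intronic positions +1,+2
    (indices 3,4) giving 10-mers; 3'ss windows (20 intronic + 3 exonic nt)
    lose intronic positions -2,-1 (indices 18,19) giving 21-mers.
    Re-stripping a stripped window raises a length error.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    expected = _PHYLO_LEN[site]
    out = []
    for w in windows:
        if len(w) != expected:
            raise ValueError(
                f"{site} window length {len(w)} != expected {expected}: {w!r}"
            )
        out.append(w[:3] + w[5:] if site == "5ss" else w[:18] + w[20:])
    return out


@dataclass(frozen=True)
class SpliceSiteClassPWM:
    """A species' splice-site PWM for one site and intron class."""

    species: str
    site: str  # 5ss | 3ss
    klass: str  # canonical | noncanonical
    pwm: PWM

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.pwm.length != _STRIPPED_LEN[self.site]:
            raise ValueError(
                f"{self.site} PWM must have {_STRIPPED_LEN[self.site]} columns, "
                f"got {self.pwm.length}"
            )

    @property
    def label(self) -> str:
        return f"{self.species}|{self.klass}"


def pwm_distance(a: PWM, b: PWM, metric: str = "frobenius") -> float:
    """Distance between two equally shaped PWMs.

    ``frobenius`` (default) is the Frobenius norm of the element-wise
    difference — symmetric, zero iff equal, and a true metric.
    ``jensen-shannon`` sums per-column JS distances instead.
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError(f"PWM shape mismatch {a.matrix.shape} vs {b.matrix.shape}")
    if metric == "frobenius":
        return float(np.linalg.norm(a.matrix - b.matrix))
    if metric == "jensen-shannon":
        total = 0.0
        for j in range(a.length):
            p, q = a.matrix[:, j], b.matrix[:, j]
            m = 0.5 * (p + q)

            def kl(x, y):
                mask = x > 0
                return float(np.sum(x[mask] * np.log2(x[mask] / y[mask])))

            total += np.sqrt(max(0.5 * kl(p, m) + 0.5 * kl(q, m), 0.0))
        return total
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over ordered labels."""

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")


def distance_matrix(
    pwms: Sequence[SpliceSiteClassPWM], metric: str = "frobenius"
) -> DistanceMatrix:
    labels = tuple(p.label for p in pwms)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate PWM labels")
    n = len(pwms)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pwm_distance(pwms[i].pwm, pwms[j].pwm, metric)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    name: str = ""
    height: float = 0.0
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        out: List[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class ClusterTree:
    """Rooted binary ultrametric tree with labelled leaves."""

    root: TreeNode
    labels: Tuple[str, ...]

    def newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{branch:.6f}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.6f}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """All root-to-leaf path lengths equal within ``tol``."""
        depths: List[float] = []

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths.append(acc)
            for child in node.children:
                walk(child, acc + node.height - child.height)

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol

    def has_clade(self, leaf_set: Iterable[str]) -> bool:
        """True iff some node's leaves are exactly ``leaf_set``."""
        target = frozenset(leaf_set)

        def walk(node: TreeNode) -> bool:
            if frozenset(node.leaf_names()) == target:
                return True
            return any(walk(c) for c in node.children)

        return walk(self.root)

    def merge_heights(self) -> List[float]:
        heights: List[float] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(heights)

    def cophenetic(self) -> Tuple[Tuple[str, ...], np.ndarray]:
        """Pairwise leaf distances (2x the height of the lowest common
        ancestor for an ultrametric tree)."""
        labels = tuple(sorted(self.root.leaf_names()))
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> List[str]:
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d = 2.0 * node.height
                            dist[index[a], index[b]] = d
                            dist[index[b], index[a]] = d
            return [name for g in groups for name in g]

        walk(self.root)
        return labels, dist


def upgma(matrix: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a distance matrix into an ultrametric tree.

    With ``average`` linkage this is classic UPGMA: the merge height is
    half the (size-weighted) average inter-cluster distance. Ties on the
    merge distance break deterministically by the lexicographically
    smallest member labels of the candidate pair. ``single`` and
    ``complete`` linkage are available as alternatives.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")

    nodes: Dict[int, TreeNode] = {
        i: TreeNode(name=matrix.labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    minlab = {i: matrix.labels[i] for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = get(i, j)
                labs = tuple(sorted((minlab[i], minlab[j])))
                key = (d, labs)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        d = best_key[0]
        first, second = (i, j) if minlab[i] <= minlab[j] else (j, i)
        parent = TreeNode(height=d / 2.0, children=[nodes[first], nodes[second]])
        nodes[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        minlab[next_id] = min(minlab[i], minlab[j])
        for k in active:
            if k in (i, j):
                continue
            if linkage == "average":
                dk = (sizes[i] * get(k, i) + sizes[j] * get(k, j)) / (
                    sizes[i] + sizes[j]
                )
            elif linkage == "single":
                dk = min(get(k, i), get(k, j))
            else:
                dk = max(get(k, i), get(k, j))
            dist[(min(k, next_id), max(k, next_id))] = dk
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1

    root = nodes[next_id - 1]
    return ClusterTree(root=root, labels=matrix.labels)


def splice_site_tree(
    profiles: Sequence[SpliceSiteClassPWM],
    site: str,
    min_class_count: int = 50,
    metric: str = "frobenius",
    linkage: str = "average",
) -> Tuple[ClusterTree, str]:
    """Cluster per-species splice-site class PWMs for one site.

    Classes built from fewer than ``min_class_count`` windows are excluded
    (poorly represented classes — a few percent of a species' introns —
    would contribute noise-dominated PWMs). Leaves are labelled
    ``species|class``. Returns the tree and its newick serialization.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    entries = [
        p for p in profiles
        if p.site == site and p.pwm.n_sequences >= min_class_count
    ]
    if len(entries) < 2:
        raise ValueError(
            f"fewer than 2 {site} PWMs remain after excluding classes with "
            f"< {min_class_count} windows"
        )
    tree = upgma(distance_matrix(entries, metric), linkage)
    return tree, tree.newick()
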