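"""Complete-linkage hierarchical clustering of sequences by E-value.

Agglomerative clustering in the spirit of the memory-frugal CLINK family:
the inter-cluster distance table lives behind a tiny get/update/delete
store interface, so an external (e.g. single-file database) store can
replace the in-memory dictionary without touching the algorithm. Distances
are log10 E-values; the "no hit" sentinel (+inf) sorts after every real
distance, so unrelated sequences only merge at infinite height.
"""

from __future__ import annotations

import math
import sqlite3
from dataclasses import dataclass, field
from typing import Iterator, Protocol

from .distances import DistanceMatrix


@dataclass(frozen=True)
class ClusterNode:
    """Node of the binary merge tree.

    Leaves have ``height == -inf`` and no children; internal nodes carry
    the complete-linkage merge height (log10 E-value scale).
    """

    accessions: tuple[str, ...]
    height: float = -math.inf
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n_leaves(self) -> int:
        return len(self.accessions)

    def iter_nodes(self) -> Iterator["ClusterNode"]:
        yield self
        if self.left is not None:
            yield from self.left.iter_nodes()
            yield from self.right.iter_nodes()


@dataclass
class ClusterTree:
    root: ClusterNode
    merge_heights: list[float] = field(default_factory=list)

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.accessions

    def iter_nodes(self) -> Iterator[ClusterNode]:
        return self.root.iter_nodes()

    def to_newick(self) -> str:
        """Newick export for inspection; infinite heights are capped."""

        def fmt(h: float) -> str:
            if not math.isfinite(h):
                return "9999"
            return f"{h:.6g}"

        def walk(node: ClusterNode, parent_h: float) -> str:
            length = fmt(parent_h) if node.is_leaf else fmt(parent_h - node.height)
            if node.is_leaf:
                return f"{node.accessions[0]}:{length}"
            inner = ",".join(walk(c, node.height) for c in (node.left, node.right))
            return f"({inner}):{length}"

        root = self.root
        if root.is_leaf:
            return f"{root.accessions[0]};"
        inner = ",".join(walk(c, root.height) for c in (root.left, root.right))
        return f"({inner});"


class DistanceStore(Protocol):
    """Minimal store interface for inter-cluster distances."""

    def get(self, a: int, b: int) -> float: ...
    def update(self, a: int, b: int, value: float) -> None: ...
    def delete_item(self, item: int) -> None: ...


class DictDistanceStore:
    """In-memory distance store."""

    def __init__(self) -> None:
        self._d: dict[tuple[int, int], float] = {}

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def get(self, a: int, b: int) -> float:
        return self._d.get(self._key(a, b), math.inf)

    def update(self, a: int, b: int, value: float) -> None:
        self._d[self._key(a, b)] = value

    def delete_item(self, item: int) -> None:
        for k in [k for k in self._d if item in k]:
            del self._d[k]


class SqliteDistanceStore:
    """Distance store persisted in a single-file (or in-memory) SQLite DB.

    Functionally interchangeable with :class:`DictDistanceStore`; exists to
    honour the negligible-main-memory contract of the clustering step.
    """

    def __init__(self, path: str = ":memory:"):
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS dist (a INTEGER, b INTEGER, d REAL, "
            "PRIMARY KEY (a, b))"
        )

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def get(self, a: int, b: int) -> float:
        a, b = self._key(a, b)
        row = self._conn.execute(
            "SELECT d FROM dist WHERE a=? AND b=?", (a, b)
        ).fetchone()
        if row is None:
            return math.inf
        return row[0] if row[0] is not None else math.inf

    def update(self, a: int, b: int, value: float) -> None:
        a, b = self._key(a, b)
        # SQLite has no +inf literal; NULL encodes the no-hit sentinel
        v = None if math.isinf(value) else value
        self._conn.execute(
            "INSERT OR REPLACE INTO dist (a, b, d) VALUES (?, ?, ?)", (a, b, v)
        )

    def delete_item(self, item: int) -> None:
        self._conn.execute("DELETE FROM dist WHERE a=? OR b=?", (item, item))

    def close(self) -> None:
        self._conn.close()


def complete_linkage(
    dist: DistanceMatrix, store: DistanceStore | None = None
) -> ClusterTree:
    """Agglomerative complete-linkage clustering.

    At each step the pair of clusters with the minimal maximum pairwise
    member distance merges; the new cluster's distance to any other cluster
    is the maximum of the two parents' distances (Lance-Williams update for
    complete linkage), which makes merge heights non-decreasing. Ties are
    broken deterministically by the sorted accession tuple of the would-be
    merged cluster, so the lexicographically smallest union merges first.

    Raises
    ------
    ValueError
        On an empty distance matrix.
    """
    items = dist.items
    if not items:
        raise ValueError("cannot cluster an empty distance matrix")
    if store is None:
        store = DictDistanceStore()

    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(accessions=(acc,)) for i, acc in enumerate(items)
    }
    # sorted member tuples for deterministic tie-breaking
    members: dict[int, tuple[str, ...]] = {
        i: (acc,) for i, acc in enumerate(items)
    }
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            store.update(i, j, dist.get(items[i], items[j]))

    next_id = len(items)
    heights: list[float] = []
    active = set(nodes)
    last_height = -math.inf
    while len(active) > 1:
        best: tuple[float, tuple[str, ...], int, int] | None = None
        act = sorted(active)
        for ai, a in enumerate(act):
            for b in act[ai + 1 :]:
                d = store.get(a, b)
                key = (d, tuple(sorted(members[a] + members[b])))
                if best is None or key < (best[0], best[1]):
                    best = (d, key[1], a, b)
        assert best is not None
        d, _, a, b = best
        height = max(d, last_height)  # guard: never below a previous merge
        last_height = height
        new = ClusterNode(
            accessions=nodes[a].accessions + nodes[b].accessions,
            height=height,
            left=nodes[a],
            right=nodes[b],
        )
        nid = next_id
        next_id += 1
        for other in active:
            if other in (a, b):
                continue
            store.update(nid, other, max(store.get(a, other), store.get(b, other)))
        store.delete_item(a)
        store.delete_item(b)
        active.discard(a)
        active.discard(b)
        active.add(nid)
        nodes[nid] = new
        members[nid] = tuple(sorted(members[a] + members[b]))
        heights.append(height)

    root = nodes[active.pop()]
    return ClusterTree(root=root, merge_heights=heights)


def select_pattern_nodes(
    tree: ClusterTree,
    min_leaves: int = 3,
    max_height: float | None = None,
) -> list[ClusterNode]:
    """Pick the tree nodes that seed pattern generation.

    Returns internal nodes with at least ``min_leaves`` leaves and merge
    height at most ``max_height``, maximal under those constraints: no
    returned node is a descendant of another, and the descent continues
    past rejected nodes so smaller compliant subclusters are still found.
    Nodes merged at the no-hit sentinel (infinite height) are never
    selected — absence of alignment evidence must not seed a pattern — so
    ``max_height=None`` means "any finite height".
    """
    cap = math.inf if max_height is None else max_height
    selected: list[ClusterNode] = []

    def walk(node: ClusterNode) -> None:
        if node.is_leaf:
            return
        if node.n_leaves >= min_leaves and node.height <= cap and math.isfinite(node.height):
            selected.append(node)
            return
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    return selected
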