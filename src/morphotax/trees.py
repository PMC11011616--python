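"""Unrooted tree topologies: newick / TNT tread IO, bipartition utilities,
exhaustive enumeration and strict consensus.

Parsimony tree length is root-invariant, so trees are handled unrooted
throughout; rooted newick strings are accepted and the root is treated as
an ordinary internal vertex (a degree-2 root is suppressed).  Polytomies
are permitted (consensus trees are usually polytomous) but search and
length computation require binary trees.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Topology",
    "enumerate_topologies",
    "n_unrooted_topologies",
    "random_topology",
    "strict_consensus",
    "read_newick",
    "read_tread",
]


class Topology:
    """An unrooted tree over named leaves.

    Internally an adjacency map over integer vertex ids; leaf vertices carry
    labels.  Equality is topological: two trees are equal iff they have the
    same leaf set and the same set of bipartitions.
    """

    def __init__(self, adj: dict[int, set[int]], leaf_label: dict[int, str]):
        self.adj = {v: set(nb) for v, nb in adj.items()}
        self.leaf_label = dict(leaf_label)
        labels = list(leaf_label.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        self._suppress_degree_two()
        self._check()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_nested(cls, nested) -> "Topology":
        """Build from nested tuples/lists of leaf names, read as unrooted:
        ``(("A","B"),("C","D"))`` is the single internal edge AB|CD."""
        adj: dict[int, set[int]] = {}
        leaf_label: dict[int, str] = {}
        counter = itertools.count()

        def build(node) -> int:
            v = next(counter)
            adj[v] = set()
            if isinstance(node, str):
                leaf_label[v] = node
                return v
            for child in node:
                c = build(child)
                adj[v].add(c)
                adj[c].add(v)
            return v

        build(nested)
        return cls(adj, leaf_label)

    @classmethod
    def star(cls, labels: Sequence[str]) -> "Topology":
        adj: dict[int, set[int]] = {0: set()}
        leaf_label: dict[int, str] = {}
        for i, lab in enumerate(labels, start=1):
            adj[0].add(i)
            adj[i] = {0}
            leaf_label[i] = lab
        return cls(adj, leaf_label)

    def copy(self) -> "Topology":
        t = object.__new__(Topology)
        t.adj = {v: set(nb) for v, nb in self.adj.items()}
        t.leaf_label = dict(self.leaf_label)
        return t

    def _check(self):
        n_vert = len(self.adj)
        n_edge = sum(len(nb) for nb in self.adj.values()) // 2
        if n_vert and n_edge != n_vert - 1:
            raise ValueError("graph is not a tree (wrong edge count)")
        # connectivity
        if self.adj:
            seen = set()
            stack = [next(iter(self.adj))]
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                stack.extend(self.adj[v] - seen)
            if len(seen) != n_vert:
                raise ValueError("graph is not connected")
        for v, lab in self.leaf_label.items():
            if len(self.adj[v]) > 1:
                raise ValueError(f"labelled vertex {lab!r} is not a leaf")

    def _suppress_degree_two(self):
        for v in [v for v in self.adj if len(self.adj[v]) == 2 and v not in self.leaf_label]:
            a, b = self.adj[v]
            self.adj[a].discard(v)
            self.adj[b].discard(v)
            self.adj[a].add(b)
            self.adj[b].add(a)
            del self.adj[v]

    # -- basic queries ---------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    @property
    def labels(self) -> list[str]:
        return sorted(self.leaf_label.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def is_binary(self) -> bool:
        """True if every internal vertex has degree 3 (unrooted binary)."""
        if self.n_leaves <= 2:
            return True
        return all(
            len(nb) == 3
            for v, nb in self.adj.items()
            if v not in self.leaf_label
        )

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in sorted(self.adj) for v in sorted(self.adj[u]) if u < v]

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each encoded as the side not containing the
        lexicographically smallest label."""
        if self.n_leaves < 4:
            return frozenset()
        ref = min(self.leaf_label.values())
        splits = set()
        # For each edge, collect leaves on the side away from the ref leaf.
        for u, v in self.edges():
            side = self._leafset_beyond(u, v)
            if ref in side:
                side = frozenset(self.leaf_label.values()) - side
            if 2 <= len(side) <= self.n_leaves - 2:
                splits.add(frozenset(side))
        return frozenset(splits)

    def _leafset_beyond(self, u: int, v: int) -> frozenset[str]:
        """Labels of leaves reachable from v without crossing edge (u,v)."""
        seen = {u, v}
        stack = [v]
        labels = set()
        while stack:
            w = stack.pop()
            if w in self.leaf_label:
                labels.add(self.leaf_label[w])
            for x in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(labels)

    def has_clade(self, labels: Iterable[str]) -> bool:
        want = frozenset(labels)
        ref = min(self.leaf_label.values())
        if ref in want:
            want = frozenset(self.leaf_label.values()) - want
        return want in self.bipartitions()

    def __eq__(self, other):
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            set(self.leaf_label.values()) == set(other.leaf_label.values())
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self):
        return hash((frozenset(self.leaf_label.values()), self.bipartitions()))

    # -- newick ----------------------------------------------------------
    def to_newick(self) -> str:
        """Serialize (unrooted; displayed rooted at an internal vertex)."""
        if not self.adj:
            return ";"
        if self.n_leaves == 1:
            return f"{next(iter(self.leaf_label.values()))};"
        # root at an internal vertex if any, else at a leaf's neighbor
        internal = [v for v in self.adj if v not in self.leaf_label]
        root = internal[0] if internal else next(iter(self.adj))

        def write(v: int, parent: int | None) -> str:
            children = [w for w in sorted(self.adj[v]) if w != parent]
            if not children:
                return _quote_label(self.leaf_label[v])
            inner = ",".join(write(w, v) for w in children)
            if v in self.leaf_label:  # labelled internal (shouldn't occur)
                return f"({inner}){_quote_label(self.leaf_label[v])}"
            return f"({inner})"

        return write(root, None) + ";"

    def __repr__(self):
        return f"Topology({self.to_newick()})"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label.replace(" ", "_")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> Topology:
    adj: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    ids: dict = {}

    def vid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = set()
        return ids[node]

    for node in dtree.preorder_node_iter():
        v = vid(node)
        if node.parent_node is not None:
            p = vid(node.parent_node)
            adj[v].add(p)
            adj[p].add(v)
        if node.is_leaf():
            leaf_label[v] = node.taxon.label if node.taxon else (node.label or "")
    return Topology(adj, leaf_label)


def read_newick(source: str) -> list[Topology]:
    """Parse one or more newick tree strings (branch lengths ignored)."""
    trees = dendropy.TreeList.get(data=source, schema="newick")
    return [_from_dendropy(t) for t in trees]


def read_tread(source: str) -> list[Topology]:
    """Parse a TNT parenthetical tree block (``tread``).

    TNT writes trees without commas, e.g. ``(A (B (C D)))``; taxa may be
    names or be separated by spaces.  Multiple trees are separated by ``*``.
    """
    m = re.search(r"\btread\b", source, flags=re.IGNORECASE)
    body = source[m.end():] if m else source
    body = re.sub(r"^\s*'[^']*'", "", body, count=1)
    body = body.split(";")[0]
    trees = []
    for chunk in body.split("*"):
        chunk = chunk.strip()
        if not chunk:
            continue
        # insert commas between sibling tokens, then reuse the newick parser
        s = re.sub(r"\)\s*\(", "),(", chunk)
        s = re.sub(r"([\w\.\-]+)\s+(?=[\w\.\-(])", r"\1,", s)
        s = re.sub(r"\)\s+(?=[\w\.\-(])", "),", s)
        trees.extend(read_newick(s + ";"))
    return trees


# ---------------------------------------------------------------------------
# Enumeration and random trees
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    if n < 3:
        return 1
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_topologies(labels: Sequence[str]) -> Iterator[Topology]:
    """Yield every unrooted binary topology on the given leaves.

    Stepwise addition: each successive leaf is attached to every edge of
    every partial topology, which enumerates each shape exactly once.
    """
    labels = list(labels)
    if len(labels) < 3:
        yield Topology.star(labels)
        return

    def grow(t: Topology, remaining: list[str]) -> Iterator[Topology]:
        if not remaining:
            yield t
            return
        lab = remaining[0]
        for u, v in t.edges():
            t2 = t.copy()
            new_internal = max(t2.adj) + 1
            new_leaf = new_internal + 1
            t2.adj[u].discard(v)
            t2.adj[v].discard(u)
            t2.adj[new_internal] = {u, v, new_leaf}
            t2.adj[u].add(new_internal)
            t2.adj[v].add(new_internal)
            t2.adj[new_leaf] = {new_internal}
            t2.leaf_label[new_leaf] = lab
            yield from grow(t2, remaining[1:])

    base = Topology.star(labels[:3])
    yield from grow(base, labels[3:])


def random_topology(labels: Sequence[str], rng) -> Topology:
    """Uniformly random unrooted binary topology via random stepwise addition."""
    labels = list(labels)
    if len(labels) < 3:
        return Topology.star(labels)
    t = Topology.star(labels[:3])
    for lab in labels[3:]:
        edges = t.edges()
        u, v = edges[rng.integers(len(edges))]
        new_internal = max(t.adj) + 1
        new_leaf = new_internal + 1
        t.adj[u].discard(v)
        t.adj[v].discard(u)
        t.adj[new_internal] = {u, v, new_leaf}
        t.adj[u].add(new_internal)
        t.adj[v].add(new_internal)
        t.adj[new_leaf] = {new_internal}
        t.leaf_label[new_leaf] = lab
    return t


# ---------------------------------------------------------------------------
# Strict consensus
# ---------------------------------------------------------------------------

def strict_consensus(trees: Sequence[Topology]) -> Topology:
    """The tree whose bipartitions are exactly those common to all inputs."""
    if not trees:
        raise ValueError("no trees given")
    leafsets = {frozenset(t.leaf_label.values()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have mismatched leaf sets")
    labels = sorted(next(iter(leafsets)))
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    return tree_from_splits(labels, common)


def tree_from_splits(labels: Sequence[str], splits: Iterable[frozenset[str]]) -> Topology:
    """Build the (possibly polytomous) unrooted tree displaying exactly the
    given pairwise-compatible splits (each encoded as the side not containing
    the smallest label)."""
    labels = sorted(labels)
    ref = labels[0]
    clusters = sorted({frozenset(s) for s in splits}, key=len, reverse=True)
    adj: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    next_id = itertools.count()
    root = next(next_id)
    adj[root] = set()
    # vertex for each cluster, nested by containment (clusters are compatible)
    cluster_vertex: dict[frozenset[str], int] = {}
    parent_of: dict[frozenset[str], int] = {}
    placed: list[frozenset[str]] = []
    for c in clusters:
        parent = root
        for p in placed:
            if c < p:
                parent = cluster_vertex[p]  # smallest superset seen last wins
        v = next(next_id)
        adj[v] = {parent}
        adj[parent].add(v)
        cluster_vertex[c] = v
        placed.append(c)
    # attach leaves
    for lab in labels:
        if lab == ref:
            parent = root
        else:
            parent = root
            best: frozenset[str] | None = None
            for c in placed:
                if lab in c and (best is None or len(c) < len(best)):
                    best = c
            if best is not None:
                parent = cluster_vertex[best]
        v = next(next_id)
        adj[v] = {parent}
        adj[parent].add(v)
        leaf_label[v] = lab
    return Topology(adj, leaf_label)
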