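"""Maximum-parsimony scoring and search.

Length is computed by dynamic programming over an arbitrarily rooted copy
of the unrooted tree: unordered characters by state-set intersection
(Fitch counting), ordered (additive) characters by interval dynamic
programming (Farris counting), vectorized over characters with numpy.
Polymorphic cells contribute their state set (respectively the closed
interval spanning their states) as the leaf assignment at zero forced
cost; missing and inapplicable cells contribute the full alphabet.

Homoplasy indices follow the usual definitions: with per-character
minimum steps m_i (best case on any tree), realized steps s_i and
maximum steps g_i (the star-tree / completely unresolved worst case),

    CI = sum(m_i) / L,   RI = (sum(g_i) - L) / (sum(g_i) - sum(m_i)),

and the implied-weighting fit of a tree is sum_i h_i / (h_i + k) with
extra steps h_i = s_i - m_i and concavity constant k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import CharacterMatrix
from .trees import (
    Topology,
    enumerate_topologies,
    random_topology,
    strict_consensus,
)

__all__ = [
    "CharacterFit",
    "TreeScore",
    "SearchResult",
    "tree_length",
    "char_min_max",
    "implied_weight_score",
    "exhaustive_search",
    "heuristic_search",
    "bremer_support",
    "MAX_EXHAUSTIVE_TAXA",
]

MAX_EXHAUSTIVE_TAXA = 9


@dataclass(frozen=True)
class CharacterFit:
    """Per-character parsimony quantities: realized steps s, best-case
    steps m, worst-case (star tree) steps g, extra steps h = s - m."""

    steps: int
    min_steps: int
    max_steps: int

    @property
    def extra_steps(self) -> int:
        return self.steps - self.min_steps


@dataclass
class TreeScore:
    """Length and homoplasy summary of one tree on one matrix."""

    length: int
    ci: float
    ri: float
    iw_score: float
    per_character: list[CharacterFit] = field(repr=False, default_factory=list)

    @property
    def sum_min(self) -> int:
        return sum(f.min_steps for f in self.per_character)

    @property
    def sum_max(self) -> int:
        return sum(f.max_steps for f in self.per_character)


@dataclass
class SearchResult:
    criterion: str
    best_score: float
    best_trees: list[Topology]
    n_starts: int = 1
    seed: int | None = None
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Leaf encodings
# ---------------------------------------------------------------------------

class _Prepped:
    """Matrix encoded for fast repeated scoring.

    Unordered characters: per-leaf uint64 bitmasks (missing = union of
    observed states).  Ordered characters: per-leaf [lo, hi] intervals
    (missing = full observed range).
    """

    def __init__(self, matrix: CharacterMatrix):
        sub = matrix.active_submatrix()
        self.labels = [str(l) for l in sub.otu_labels]
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n_otus, n_chars = sub.n_otus, sub.n_characters
        unordered_cols = [j for j in range(n_chars) if not sub.ordered_flags[j]]
        ordered_cols = [j for j in range(n_chars) if sub.ordered_flags[j]]
        self.unordered_cols = unordered_cols
        self.ordered_cols = ordered_cols
        self.n_characters = n_chars

        # unordered: bitmasks
        self.masks = np.zeros((n_otus, len(unordered_cols)), dtype=np.uint64)
        for cj, j in enumerate(unordered_cols):
            observed = set()
            for i in range(n_otus):
                observed |= sub.cells[i][j].states
            full = 0
            for s in observed:
                full |= 1 << s
            if full == 0:
                full = 1  # never-scored character: inert single state
            for i in range(n_otus):
                cell = sub.cells[i][j]
                if cell.is_scored:
                    m = 0
                    for s in cell.states:
                        m |= 1 << s
                else:
                    m = full
                self.masks[i, cj] = m

        # ordered: intervals
        self.lo = np.zeros((n_otus, len(ordered_cols)), dtype=np.int64)
        self.hi = np.zeros((n_otus, len(ordered_cols)), dtype=np.int64)
        for cj, j in enumerate(ordered_cols):
            observed = set()
            for i in range(n_otus):
                observed |= sub.cells[i][j].states
            omin, omax = (min(observed), max(observed)) if observed else (0, 0)
            for i in range(n_otus):
                cell = sub.cells[i][j]
                if cell.is_scored:
                    self.lo[i, cj] = min(cell.states)
                    self.hi[i, cj] = max(cell.states)
                else:
                    self.lo[i, cj] = omin
                    self.hi[i, cj] = omax

        self.cells = sub.cells
        self.ordered_flags = sub.ordered_flags

    def steps_per_character(self, tree: Topology) -> np.ndarray:
        """Realized steps s_i for every character (original column order)."""
        order, children, root, root_leaf = _rooted_structure(tree, self.index)
        n = len(self.labels)

        s = np.zeros(self.n_characters, dtype=np.int64)

        # ---- unordered: Fitch state-set DP ----
        if self.masks.shape[1]:
            nodes_masks: dict[int, np.ndarray] = {}
            steps_u = np.zeros(self.masks.shape[1], dtype=np.int64)
            for v in order:
                if v < n:  # leaf id = row index
                    nodes_masks[v] = self.masks[v]
                    continue
                a, b = children[v]
                ma, mb = nodes_masks[a], nodes_masks[b]
                inter = ma & mb
                empty = inter == 0
                steps_u += empty
                nodes_masks[v] = np.where(empty, ma | mb, inter)
                del nodes_masks[a], nodes_masks[b]
            # combine with the root leaf
            inter = nodes_masks[root] & self.masks[root_leaf]
            steps_u += inter == 0
            for cj, j in enumerate(self.unordered_cols):
                s[j] = steps_u[cj]

        # ---- ordered: Farris interval DP ----
        if self.lo.shape[1]:
            nodes_lo: dict[int, np.ndarray] = {}
            nodes_hi: dict[int, np.ndarray] = {}
            steps_o = np.zeros(self.lo.shape[1], dtype=np.int64)
            for v in order:
                if v < n:
                    nodes_lo[v] = self.lo[v]
                    nodes_hi[v] = self.hi[v]
                    continue
                a, b = children[v]
                lo1, hi1 = nodes_lo[a], nodes_hi[a]
                lo2, hi2 = nodes_lo[b], nodes_hi[b]
                ilo = np.maximum(lo1, lo2)
                ihi = np.minimum(hi1, hi2)
                gap = ilo - ihi  # positive iff disjoint
                disjoint = gap > 0
                steps_o += np.where(disjoint, gap, 0)
                # overlap -> intersection; disjoint -> the between-interval
                nodes_lo[v] = np.where(disjoint, ihi, ilo)
                nodes_hi[v] = np.where(disjoint, ilo, ihi)
                for d in (a, b):
                    del nodes_lo[d], nodes_hi[d]
            lo1, hi1 = nodes_lo[root], nodes_hi[root]
            lo2, hi2 = self.lo[root_leaf], self.hi[root_leaf]
            gap = np.maximum(lo1, lo2) - np.minimum(hi1, hi2)
            steps_o += np.where(gap > 0, gap, 0)
            for cj, j in enumerate(self.ordered_cols):
                s[j] = steps_o[cj]

        return s

    def length(self, tree: Topology) -> int:
        return int(self.steps_per_character(tree).sum())


def _rooted_structure(tree: Topology, index: dict[str, int]):
    """Root the unrooted binary tree at a leaf edge; return a postorder of
    vertex ids (leaves relabelled to matrix row indices), a children map for
    internal vertices, the root vertex and the root leaf's row index."""
    leaves = set(tree.leaf_label.values())
    if leaves != set(index):
        missing = leaves ^ set(index)
        raise ValueError(f"tree leaves do not match active OTUs: {sorted(missing)}")
    if not tree.is_binary():
        raise ValueError("tree must be binary for length computation")
    n = len(index)
    if n == 1:
        raise ValueError("need at least 2 leaves")

    # map topology vertices to ids: leaves -> row index, internals -> n, n+1...
    vmap: dict[int, int] = {}
    counter = itertools.count(n)
    for v, lab in tree.leaf_label.items():
        vmap[v] = index[lab]

    leaf0 = next(v for v, lab in tree.leaf_label.items() if index[lab] == 0)
    if n == 2:
        other = next(iter(tree.adj[leaf0]))
        return [vmap[other]], {}, vmap[other], 0

    root_t = next(iter(tree.adj[leaf0]))  # internal vertex adjacent to leaf 0
    order: list[int] = []
    children: dict[int, tuple[int, int]] = {}

    def vid(v: int) -> int:
        if v not in vmap:
            vmap[v] = next(counter)
        return vmap[v]

    stack = [(root_t, leaf0, False)]
    while stack:
        v, parent, expanded = stack.pop()
        if expanded:
            kids = [vid(w) for w in tree.adj[v] if w != parent]
            children[vid(v)] = (kids[0], kids[1])
            order.append(vid(v))
            continue
        if v in tree.leaf_label:
            order.append(vid(v))
            continue
        stack.append((v, parent, True))
        for w in tree.adj[v]:
            if w != parent:
                stack.append((w, v, False))

    return order, children, vmap[root_t], 0


# ---------------------------------------------------------------------------
# Per-character best / worst case steps
# ---------------------------------------------------------------------------

def char_min_max(matrix: CharacterMatrix) -> list[tuple[int, int]]:
    """(m_i, g_i) per active character of the active submatrix.

    m_i is the minimum steps achievable on any tree; g_i the steps on the
    completely unresolved bush (star tree).  Polymorphic cells may commit
    to whichever contained state minimizes the quantity.
    """
    sub = matrix.active_submatrix()
    out: list[tuple[int, int]] = []
    for j in range(sub.n_characters):
        cells = [sub.cells[i][j] for i in range(sub.n_otus)]
        scored = [c for c in cells if c.is_scored]
        if len(scored) <= 1:
            out.append((0, 0))
            continue
        if sub.ordered_flags[j]:
            out.append(_min_max_ordered(scored))
        else:
            out.append(_min_max_unordered(scored))
    return out


def _min_max_unordered(scored) -> tuple[int, int]:
    observed = sorted(set().union(*[c.states for c in scored]))
    # m: smallest state set hitting every cell, minus one (set cover over a
    # tiny alphabet; exhaustive over subset sizes)
    m = len(observed) - 1
    for t in range(1, len(observed) + 1):
        found = False
        for combo in itertools.combinations(observed, t):
            cs = set(combo)
            if all(cs & c.states for c in scored):
                found = True
                break
        if found:
            m = t - 1
            break
    # g: star tree — best central state leaves the cells not containing it
    g = len(scored) - max(
        sum(1 for c in scored if s in c.states) for s in observed
    )
    return m, g


def _min_max_ordered(scored) -> tuple[int, int]:
    los = [min(c.states) for c in scored]
    his = [max(c.states) for c in scored]
    # m: minimal spanned range after committing polymorphic cells
    m = max(0, max(los) - min(his))
    # g: best median state on the star tree
    lo_all, hi_all = min(los), max(his)
    g = min(
        sum(
            (lo - c) if c < lo else ((c - hi) if c > hi else 0)
            for lo, hi in zip(los, his)
        )
        for c in range(lo_all, hi_all + 1)
    )
    return m, g


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _character_k(
    matrix: CharacterMatrix, k: float, extended: bool, k_min: float = 0.1
) -> np.ndarray:
    """Per-character concavity constants.

    Standard implied weighting uses a single k.  The extended variant
    downweights characters with missing entries faster: here via the
    monotone map k_i = max(k_min, k * (1 - f_i)) with f_i the fraction of
    unscored cells among active OTUs, so a fully scored character keeps k
    and increasingly incomplete characters get harsher (smaller) constants.
    """
    sub = matrix.active_submatrix()
    if not extended:
        return np.full(sub.n_characters, float(k))
    ks = np.empty(sub.n_characters)
    for j in range(sub.n_characters):
        n_missing = sum(
            0 if sub.cells[i][j].is_scored else 1 for i in range(sub.n_otus)
        )
        f = n_missing / sub.n_otus
        ks[j] = max(k_min, k * (1.0 - f))
    return ks


def tree_length(
    matrix: CharacterMatrix,
    tree: Topology,
    k: float = 9.0,
    extended: bool = False,
    informative_only: bool = False,
    resolve_polytomies: bool = False,
) -> TreeScore:
    """Score one tree: length, CI, RI, implied-weighting fit, per-character
    breakdown.

    ``informative_only`` restricts CI/RI to characters with m_i < g_i
    (the parsimony-informative ones).  ``resolve_polytomies`` accepts a
    polytomous tree and returns the minimum over all binary resolutions
    (brute force; small trees only).
    """
    if not tree.is_binary():
        if not resolve_polytomies:
            raise ValueError(
                "polytomous tree: length requires a binary tree "
                "(pass resolve_polytomies=True for the brute-force minimum)"
            )
        if tree.n_leaves > MAX_EXHAUSTIVE_TAXA:
            raise ValueError("resolve_polytomies only supported for small trees")
        want = tree.bipartitions()
        best = None
        for cand in enumerate_topologies(tree.labels):
            if want <= cand.bipartitions():
                sc = tree_length(matrix, cand, k, extended, informative_only)
                if best is None or sc.length < best.length:
                    best = sc
        assert best is not None
        return best

    prep = _Prepped(matrix)
    s = prep.steps_per_character(tree)
    mg = char_min_max(matrix)
    fits = [CharacterFit(int(si), m, g) for si, (m, g) in zip(s, mg)]

    sel = fits
    if informative_only:
        sel = [f for f in fits if f.min_steps < f.max_steps]
    L = int(sum(f.steps for f in fits))
    L_sel = int(sum(f.steps for f in sel))
    sum_m = sum(f.min_steps for f in sel)
    sum_g = sum(f.max_steps for f in sel)
    ci = sum_m / L_sel if L_sel > 0 else float("nan")
    ri = (sum_g - L_sel) / (sum_g - sum_m) if sum_g > sum_m else float("nan")

    ks = _character_k(matrix, k, extended)
    h = np.array([f.extra_steps for f in fits], dtype=float)
    iw = float(np.sum(h / (h + ks)))
    return TreeScore(length=L, ci=ci, ri=ri, iw_score=iw, per_character=fits)


def implied_weight_score(
    matrix: CharacterMatrix,
    tree: Topology,
    k: float = 9.0,
    extended: bool = False,
    missing_downweight: bool | None = None,
) -> float:
    """Implied-weighting fit sum_i h_i/(h_i + k_i) (lower is better).

    ``missing_downweight`` is an alias for ``extended`` kept for symmetry
    with the analysis settings; if given it takes precedence.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if missing_downweight is not None:
        extended = missing_downweight
    return tree_length(matrix, tree, k=k, extended=extended).iw_score


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _criterion_fn(prep: _Prepped, matrix: CharacterMatrix, criterion: str, k: float,
                  extended: bool):
    if criterion == "length":
        return lambda t: float(prep.steps_per_character(t).sum())
    if criterion in ("iw", "implied", "implied_weighting"):
        mg = char_min_max(matrix)
        m = np.array([a for a, _ in mg], dtype=float)
        ks = _character_k(matrix, k, extended)

        def fit(t: Topology) -> float:
            s = prep.steps_per_character(t).astype(float)
            h = np.maximum(s - m, 0.0)
            return float(np.sum(h / (h + ks)))

        return fit
    raise ValueError(f"unknown criterion {criterion!r}")


def exhaustive_search(
    matrix: CharacterMatrix,
    criterion: str = "length",
    k: float = 9.0,
    extended: bool = False,
) -> SearchResult:
    """Enumerate every unrooted binary topology on the active OTUs and
    return all optima.  Limited to ``MAX_EXHAUSTIVE_TAXA`` taxa."""
    prep = _Prepped(matrix)
    labels = prep.labels
    if len(labels) > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"{len(labels)} taxa exceed the exhaustive cap of {MAX_EXHAUSTIVE_TAXA}"
        )
    score = _criterion_fn(prep, matrix, criterion, k, extended)
    best: float | None = None
    best_trees: list[Topology] = []
    n_seen = 0
    for t in enumerate_topologies(labels):
        n_seen += 1
        sc = score(t)
        if best is None or sc < best - 1e-12:
            best = sc
            best_trees = [t]
        elif abs(sc - best) <= 1e-12:
            best_trees.append(t)
    assert best is not None
    return SearchResult(
        criterion=criterion,
        best_score=best,
        best_trees=best_trees,
        log=[f"enumerated {n_seen} topologies"],
    )


def _tbr_neighbors(tree: Topology):
    """Yield all tree-bisection-reconnection neighbors of a binary tree.

    Every edge is broken; the two resulting subtrees are reconnected by a
    new edge between every pair of (possibly subdivided) edges, one in each
    part.  Includes all SPR and NNI rearrangements as special cases.
    """
    labels_n = tree.n_leaves
    for u, v in tree.edges():
        # split into component containing u and component containing v
        part_u = _component(tree, u, v)
        part_v = _component(tree, v, u)
        att_u = _attachment_points(tree, part_u, u)
        att_v = _attachment_points(tree, part_v, v)
        for a in att_u:
            for b in att_v:
                t2 = _reconnect(tree, u, v, part_u, part_v, a, b)
                if t2 is not None:
                    yield t2


def _component(tree: Topology, start: int, banned: int) -> set[int]:
    seen = {banned, start}
    stack = [start]
    comp = {start}
    while stack:
        w = stack.pop()
        for x in tree.adj[w]:
            if x not in seen:
                seen.add(x)
                comp.add(x)
                stack.append(x)
    return comp


def _attachment_points(tree: Topology, comp: set[int], cut_end: int):
    """Edges of the component usable as reattachment sites, after the cut
    vertex is suppressed.  A single-vertex component attaches at the vertex."""
    if len(comp) == 1:
        return [(start := next(iter(comp)), start)]
    # edges within comp, in the tree with cut_end suppressed if degree-2
    nb = [w for w in tree.adj[cut_end] if w in comp]
    edges = []
    for x in comp:
        for y in tree.adj[x]:
            if y in comp and x < y:
                edges.append((x, y))
    if len(nb) == 2:
        a, b = nb
        # suppressing cut_end merges edges (cut_end,a) and (cut_end,b)
        edges = [e for e in edges if cut_end not in e]
        edges.append((min(a, b), max(a, b)))
    return edges


def _reconnect(tree, u, v, part_u, part_v, edge_a, edge_b):
    t = tree.copy()
    # remove the bisected edge
    t.adj[u].discard(v)
    t.adj[v].discard(u)
    next_id = max(t.adj) + 1

    def attach(cut_end, comp, edge):
        """Suppress the old cut vertex if needed and return the vertex that
        the new connecting edge should end at."""
        nonlocal next_id
        if len(comp) == 1:
            return next(iter(comp))
        nb = [w for w in t.adj[cut_end] if w in comp]
        if cut_end in t.leaf_label:
            # cut at a leaf's edge: the leaf is its own attachment vertex
            if edge == (cut_end, cut_end):
                return cut_end
        if len(nb) == 2:
            a, b = nb
            t.adj[a].discard(cut_end)
            t.adj[b].discard(cut_end)
            t.adj[a].add(b)
            t.adj[b].add(a)
            del t.adj[cut_end]
            merged = (min(a, b), max(a, b))
        else:
            merged = None
        x, y = edge
        if x == y:  # attach directly at a vertex (single-leaf component)
            return x
        if merged is not None and cut_end in (x, y):
            x, y = merged
        # subdivide edge (x, y)
        w = next_id
        next_id += 1
        t.adj[x].discard(y)
        t.adj[y].discard(x)
        t.adj[w] = {x, y}
        t.adj[x].add(w)
        t.adj[y].add(w)
        return w

    end_a = attach(u, part_u, edge_a)
    end_b = attach(v, part_v, edge_b)
    t.adj[end_a].add(end_b)
    t.adj[end_b].add(end_a)
    try:
        return Topology(t.adj, t.leaf_label)
    except ValueError:
        return None


def _random_addition_tree(prep: _Prepped, matrix: CharacterMatrix, rng,
                          score_subset) -> Topology:
    """Greedy stepwise addition in a random leaf order."""
    labels = list(prep.labels)
    rng.shuffle(labels)
    tree = Topology.star(labels[:3])
    for lab in labels[3:]:
        best_score = None
        best_tree = None
        for u, v in tree.edges():
            t2 = tree.copy()
            new_internal = max(t2.adj) + 1
            new_leaf = new_internal + 1
            t2.adj[u].discard(v)
            t2.adj[v].discard(u)
            t2.adj[new_internal] = {u, v, new_leaf}
            t2.adj[u].add(new_internal)
            t2.adj[v].add(new_internal)
            t2.adj[new_leaf] = {new_internal}
            t2.leaf_label[new_leaf] = lab
            sc = score_subset(t2)
            if best_score is None or sc < best_score:
                best_score = sc
                best_tree = t2
        tree = best_tree
    return tree


def heuristic_search(
    matrix: CharacterMatrix,
    criterion: str = "length",
    n_starts: int = 5,
    seed: int | None = None,
    k: float = 9.0,
    extended: bool = False,
    keep_cap: int = 10_000,
    max_rounds: int = 200,
) -> SearchResult:
    """Random-addition starting trees followed by tree-bisection-
    reconnection hill climbing; all equally optimal trees found are
    retained (first-found order) up to ``keep_cap``.

    Reproducible for a given ``seed``; the seed is mandatory so that
    replicate logs are meaningful.
    """
    if seed is None:
        raise ValueError("heuristic_search requires an explicit seed")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    prep = _Prepped(matrix)
    score = _criterion_fn(prep, matrix, criterion, k, extended)

    # scoring of partial trees during stepwise addition: restrict rows
    def score_subset(t: Topology) -> float:
        rows = [prep.index[lab] for lab in t.leaf_label.values()]
        sub_prep = _subset_view(prep, sorted(rows))
        return float(sub_prep.steps_per_character(t).sum())

    best_global: float | None = None
    pool: list[Topology] = []
    pool_keys: set = set()
    log: list[str] = []

    for start in range(n_starts):
        tree = _random_addition_tree(prep, matrix, rng, score_subset)
        current = score(tree)
        for _round in range(max_rounds):
            improved = False
            equal_here: list[Topology] = []
            for nb in _tbr_neighbors(tree):
                sc = score(nb)
                if sc < current - 1e-12:
                    tree, current = nb, sc
                    improved = True
                    break  # first-improvement restart of the scan
                elif abs(sc - current) <= 1e-12:
                    equal_here.append(nb)
            if not improved:
                break
        log.append(f"start {start}: local optimum {current}")
        if best_global is None or current < best_global - 1e-12:
            best_global = current
            pool, pool_keys = [], set()
        if abs(current - best_global) <= 1e-12:
            for t in [tree] + equal_here:
                key = (frozenset(t.leaf_label.values()), t.bipartitions())
                if key not in pool_keys and len(pool) < keep_cap:
                    pool_keys.add(key)
                    pool.append(t)

    assert best_global is not None
    return SearchResult(
        criterion=criterion,
        best_score=best_global,
        best_trees=pool,
        n_starts=n_starts,
        seed=seed,
        log=log,
    )


def _subset_view(prep: _Prepped, rows: list[int]) -> _Prepped:
    """A row-subset view of a prepped matrix (for partial-tree scoring)."""
    view = object.__new__(_Prepped)
    view.labels = [prep.labels[i] for i in rows]
    view.index = {lab: i for i, lab in enumerate(view.labels)}
    view.unordered_cols = prep.unordered_cols
    view.ordered_cols = prep.ordered_cols
    view.n_characters = prep.n_characters
    view.masks = prep.masks[rows]
    view.lo = prep.lo[rows]
    view.hi = prep.hi[rows]
    return view


# ---------------------------------------------------------------------------
# Bremer (decay) support
# ---------------------------------------------------------------------------

def bremer_support(
    matrix: CharacterMatrix,
    best_trees: list[Topology] | None = None,
    max_extra_steps: int = 5,
    seed: int | None = None,
) -> dict[frozenset[str], int | None]:
    """Decay index per consensus clade: the smallest extra length at which
    the clade collapses from the strict consensus of all trees within that
    length bound.  ``None`` means the clade persisted through the whole
    examined bound (its decay exceeds ``max_extra_steps``).

    With at most ``MAX_EXHAUSTIVE_TAXA`` active taxa every topology is
    enumerated, making the values exact; larger matrices use a heuristic
    search pool with relaxed optimality retention and the values are upper
    bounds on what a fuller search might find.
    """
    if max_extra_steps < 1:
        raise ValueError("max_extra_steps must be >= 1")
    prep = _Prepped(matrix)
    labels = prep.labels

    scored: list[tuple[float, Topology]] = []
    if len(labels) <= MAX_EXHAUSTIVE_TAXA:
        for t in enumerate_topologies(labels):
            scored.append((float(prep.steps_per_character(t).sum()), t))
        best_len = min(sc for sc, _ in scored)
    else:
        if best_trees is None:
            res = heuristic_search(matrix, "length", n_starts=3,
                                   seed=seed if seed is not None else 0)
            best_trees = res.best_trees
        best_len = float(prep.steps_per_character(best_trees[0]).sum())
        seen = set()
        # pool: relaxed-retention TBR sweep around the optimal trees
        frontier = list(best_trees)
        while frontier:
            t = frontier.pop()
            key = t.bipartitions()
            if key in seen:
                continue
            seen.add(key)
            sc = float(prep.steps_per_character(t).sum())
            if sc <= best_len + max_extra_steps:
                scored.append((sc, t))
                if len(seen) < 2000:
                    frontier.extend(
                        nb for nb in _tbr_neighbors(t)
                        if nb.bipartitions() not in seen
                    )

    optima = [t for sc, t in scored if sc <= best_len + 1e-9]
    consensus = strict_consensus(optima)
    out: dict[frozenset[str], int | None] = {}
    for clade in consensus.bipartitions():
        value: int | None = None
        for d in range(1, max_extra_steps + 1):
            within = [t for sc, t in scored if sc <= best_len + d + 1e-9]
            if clade not in strict_consensus(within).bipartitions():
                value = d
                break
        out[clade] = value
    return out
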