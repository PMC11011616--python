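"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from morphotax.model import CellScore, CharacterMatrix


def random_matrix(
    n_taxa: int = 5,
    n_chars: int = 6,
    seed: int = 0,
    n_states: int = 3,
    missing_rate: float = 0.15,
    polymorphism_rate: float = 0.1,
    ordered_first: int = 2,
) -> CharacterMatrix:
    """Small random matrix for fuzzing (independent of the package's own
    simulator so the two can cross-check each other)."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _j in range(n_chars):
            u = rng.random()
            if u < missing_rate:
                row.append(CellScore.missing())
            elif u < missing_rate + polymorphism_rate:
                pair = rng.choice(n_states, size=2, replace=False)
                row.append(CellScore.scored(*(int(x) for x in pair)))
            else:
                row.append(CellScore.scored(int(rng.integers(0, n_states))))
        cells.append(row)
    flags = [j < ordered_first for j in range(n_chars)]
    return CharacterMatrix(labels, n_chars, cells, flags)


def brute_force_length(matrix: CharacterMatrix, tree) -> int:
    """Tree length by exhaustive enumeration of every internal-state (and
    polymorphic-leaf-state) assignment — the definitional minimum-mutation
    count, independent of the dynamic programming implementation."""
    sub = matrix.active_submatrix()
    idx = {lab: i for i, lab in enumerate(sub.otu_labels)}
    internals = [v for v in tree.adj if v not in tree.leaf_label]
    leaf_vs = [v for v in tree.adj if v in tree.leaf_label]
    edges = tree.edges()
    total = 0
    for j in range(sub.n_characters):
        observed = set()
        for i in range(sub.n_otus):
            observed |= sub.cells[i][j].states
        if not observed:
            continue
        ordered = sub.ordered_flags[j]
        if ordered:
            allstates = list(range(min(observed), max(observed) + 1))
        else:
            allstates = sorted(observed)

        def leaf_opts(v):
            c = sub.cells[idx[tree.leaf_label[v]]][j]
            if not c.is_scored:
                return allstates
            if ordered:
                return list(range(min(c.states), max(c.states) + 1))
            return sorted(c.states)

        best = None
        for internal_assign in itertools.product(allstates, repeat=len(internals)):
            amap = dict(zip(internals, internal_assign))
            for leaf_assign in itertools.product(*[leaf_opts(v) for v in leaf_vs]):
                amap.update(zip(leaf_vs, leaf_assign))
                cost = 0
                for u, v in edges:
                    cost += (
                        abs(amap[u] - amap[v]) if ordered else int(amap[u] != amap[v])
                    )
                if best is None or cost < best:
                    best = cost
        total += best
    return total


@pytest.fixture
def toy_matrix() -> CharacterMatrix:
    """The 2-OTU, 4-character hand-parsed example."""
    from morphotax.io import read_tnt

    return read_tnt("xread 4 2 A 01?0 B 0[01]-1")
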