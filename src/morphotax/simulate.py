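"""Synthetic matrices, trees, planted comparison pairs and measurement
tables with known ground truth.

The generator emulates a fossil morphological matrix: discrete characters
with 2-6 states evolved independently on a known tree, a designated
ordered subset stepping +/-1 between adjacent states, heavy missingness
(30-70% of cells in the realistic regime), and occasional polymorphic
cells.  Branch lengths are expected numbers of changes per character, the
simplest calibration for parsimony-recovery experiments.

Missingness is uniform at random by default; ``block_missing`` instead
deletes contiguous character ranges per OTU, mimicking element-wise
preservation (a specimen either preserves a bone and is scorable for all
of that bone's characters, or lacks it entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CellScore, CharacterMatrix
from .trees import Topology, random_topology

__all__ = [
    "SimulationConfig",
    "generate_matrix",
    "plant_pair",
    "generate_measurements",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated matrix; the seed is mandatory."""

    n_taxa: int = 20
    n_characters: int = 100
    seed: int = 0
    n_states: int = 3  # states per character (2-6 typical)
    mean_branch_length: float = 0.3  # expected changes per character per branch
    ordered_fraction: float = 0.05
    missing_rate: float = 0.5
    polymorphism_rate: float = 0.01
    block_missing: bool = False
    noise_free: bool = False  # homoplasy-free split characters instead of Markov
    tree: Topology | None = None  # evolve on this tree instead of a random one

    def __post_init__(self):
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0 <= self.polymorphism_rate <= 1:
            raise ValueError("polymorphism_rate must be in [0, 1]")
        if not 0 <= self.ordered_fraction <= 1:
            raise ValueError("ordered_fraction must be in [0, 1]")
        if not 2 <= self.n_states <= 32:
            raise ValueError("n_states must be in 2..32")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def generate_matrix(config: SimulationConfig) -> tuple[CharacterMatrix, Topology]:
    """Evolve a matrix on a known tree; returns (matrix, true_tree).

    Each character evolves under a symmetric Markov change process: the
    number of changes on a branch is Poisson with mean equal to the branch
    length, and each change picks a uniformly random different state
    (ordered characters instead step +/-1, reflecting at the ends of the
    state ladder).  Byte-identical output for a given config.
    """
    rng = np.random.default_rng(config.seed)
    labels = [f"otu{i:03d}" for i in range(config.n_taxa)]
    tree = config.tree if config.tree is not None else random_topology(labels, rng)
    if sorted(tree.leaf_label.values()) != sorted(labels) and config.tree is not None:
        labels = sorted(tree.leaf_label.values())

    n_chars = config.n_characters
    n_ordered = int(round(config.ordered_fraction * n_chars))
    ordered_flags = [j < n_ordered for j in range(n_chars)]

    if config.noise_free:
        return _generate_noise_free(config, tree, rng)

    # root the true tree at an arbitrary leaf and evolve down the edges
    root = next(iter(tree.leaf_label))
    order: list[tuple[int, int]] = []  # (parent, child) edges in preorder
    seen = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for w in tree.adj[v]:
            if w not in seen:
                seen.add(w)
                order.append((v, w))
                stack.append(w)

    k = config.n_states
    states: dict[int, np.ndarray] = {
        root: rng.integers(0, k, size=n_chars)
    }
    for parent, child in order:
        blen = rng.exponential(config.mean_branch_length)
        n_changes = rng.poisson(blen, size=n_chars)
        s = states[parent].copy()
        for j in np.nonzero(n_changes)[0]:
            for _ in range(n_changes[j]):
                if ordered_flags[j]:
                    if s[j] == 0:
                        s[j] = 1
                    elif s[j] == k - 1:
                        s[j] = k - 2
                    else:
                        s[j] += rng.choice([-1, 1])
                else:
                    s[j] = (s[j] + rng.integers(1, k)) % k
        states[child] = s

    # assemble leaf rows, then apply polymorphism and missingness
    label_order = sorted(tree.leaf_label.values())
    leaf_vertex = {lab: v for v, lab in tree.leaf_label.items()}
    cells: list[list[CellScore]] = []
    for lab in label_order:
        s = states[leaf_vertex[lab]]
        row: list[CellScore] = []
        for j in range(n_chars):
            st = {int(s[j])}
            if rng.random() < config.polymorphism_rate:
                if ordered_flags[j]:  # adjacent state
                    extra = int(s[j]) + (1 if s[j] < k - 1 else -1)
                else:
                    extra = int((s[j] + rng.integers(1, k)) % k)
                st.add(extra)
            row.append(CellScore.scored(*st))
        cells.append(row)

    if config.block_missing and config.missing_rate > 0:
        # delete contiguous character blocks per OTU until the target rate
        block = max(1, n_chars // 10)
        for row in cells:
            target = int(round(config.missing_rate * n_chars))
            removed = 0
            while removed < target:
                start = int(rng.integers(0, n_chars))
                for j in range(start, min(start + block, n_chars)):
                    if row[j].is_scored:
                        row[j] = CellScore.missing()
                        removed += 1
                        if removed >= target:
                            break
    elif config.missing_rate > 0:
        miss = rng.random((len(cells), n_chars)) < config.missing_rate
        for i, row in enumerate(cells):
            for j in range(n_chars):
                if miss[i, j]:
                    row[j] = CellScore.missing()

    matrix = CharacterMatrix(label_order, n_chars, cells, list(ordered_flags))
    return matrix, tree


def _generate_noise_free(
    config: SimulationConfig, tree: Topology, rng
) -> tuple[CharacterMatrix, Topology]:
    """Homoplasy-free matrix: each character is a clean binary split along
    one internal edge of the true tree (state 1 on one side, 0 on the
    other).  Internal edges are cycled so that every edge is marked by at
    least one character when n_characters >= n_taxa - 3; the generating
    tree is then the unique most parsimonious tree and RI = 1 on it."""
    n_chars = config.n_characters
    label_order = sorted(tree.leaf_label.values())
    n = len(label_order)
    splits = sorted(
        (sorted(s) for s in tree.bipartitions()), key=lambda s: (len(s), s)
    )
    if not splits:
        raise ValueError("noise-free mode needs at least 4 taxa")
    cells: list[list[CellScore]] = [[] for _ in label_order]
    for j in range(n_chars):
        side = set(splits[j % len(splits)])
        for i, lab in enumerate(label_order):
            cells[i].append(CellScore.scored(1 if lab in side else 0))
    if config.missing_rate > 0:
        miss = rng.random((n, n_chars)) < config.missing_rate
        for i in range(n):
            for j in range(n_chars):
                if miss[i, j]:
                    cells[i][j] = CellScore.missing()
    matrix = CharacterMatrix(label_order, n_chars, cells)
    return matrix, tree


def plant_pair(
    matrix: CharacterMatrix,
    base_otu: str,
    n_green: int,
    n_yellow: int,
    n_blue: int,
    seed: int,
    new_label: str = "planted",
) -> CharacterMatrix:
    """Add one OTU whose comparison against ``base_otu`` yields exactly
    (n_green, n_yellow, n_blue); all its other cells are missing.

    Green cells copy the base score set; yellow cells keep one base state
    and add a new one (intersecting but unequal); blue cells use a state
    set disjoint from the base cell's.
    """
    rng = np.random.default_rng(seed)
    base = matrix.row(base_otu)
    scored_idx = [j for j, c in enumerate(base) if c.is_scored]
    need = n_green + n_yellow + n_blue
    if len(scored_idx) < need:
        raise ValueError(
            f"base OTU has {len(scored_idx)} scored cells, need {need}"
        )
    chosen = rng.choice(len(scored_idx), size=need, replace=False)
    chosen = [scored_idx[int(i)] for i in chosen]
    greens = set(chosen[:n_green])
    yellows = set(chosen[n_green : n_green + n_yellow])
    blues = set(chosen[n_green + n_yellow :])

    new_row: list[CellScore] = []
    for j, cell in enumerate(base):
        if j in greens:
            new_row.append(cell)
        elif j in yellows:
            keep = min(cell.states)
            extra = max(cell.states) + 1  # guaranteed outside the base set
            new_row.append(CellScore.scored(keep, extra))
        elif j in blues:
            new_row.append(CellScore.scored(max(cell.states) + 1))
        else:
            new_row.append(CellScore.missing())

    out = matrix.copy()
    out.otu_labels.append(new_label)
    out.cells.append(new_row)
    out.active_otus.append(True)
    return out


def generate_measurements(n: int, seed: int) -> list[dict]:
    """Vertebral centrum measurement rows with precomputed elongation
    indices spanning the realistic 0.3-3.0 range.

    Each row carries (L, W, H) in mm plus the aEI value they imply, so a
    recomputation can be checked against stored truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        target = rng.uniform(0.3, 3.0)
        width = rng.uniform(50.0, 400.0)
        height = width * rng.uniform(0.7, 1.3)
        length = target * (width + height) / 2.0
        rows.append(
            {
                "specimen": f"syn{i:04d}",
                "element": "caudal_vertebra",
                "L_mm": round(length, 3),
                "W_mm": round(width, 3),
                "H_mm": round(height, 3),
                "incomplete": bool(rng.random() < 0.2),
                "aei_true": round(length, 3) / ((round(width, 3) + round(height, 3)) / 2.0),
            }
        )
    return rows
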