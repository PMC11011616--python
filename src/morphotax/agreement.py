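"""Pairwise character-agreement statistics between OTUs and threshold-based
taxonomic delimitation.

For two OTUs, every character scored in both is placed in one of three
categories by comparing the two state sets:

* green  — identical sets (full agreement),
* yellow — intersecting but unequal sets (partial agreement, e.g. ``0``
  against ``0&1``),
* blue   — disjoint sets (outright disagreement).

The delimitation rule follows the specimen-level practice of counting
character differences between name-bearing specimens: at least 6
differences separate species, at least 13 separate genera.  Both a strict
difference percentage (blue / overlap) and a half-credit variant
((blue + yellow/2) / overlap) are reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .model import CharacterMatrix, MatrixError

__all__ = [
    "PairwiseComparison",
    "DelimitationResult",
    "compare_pair",
    "difference_percent",
    "delimit",
    "pairwise_table",
    "UndefinedPercentageError",
    "SPECIES_THRESHOLD",
    "GENUS_THRESHOLD",
]

SPECIES_THRESHOLD = 6
GENUS_THRESHOLD = 13


class UndefinedPercentageError(MatrixError):
    """Difference percentage requested for a pair with zero overlap."""


@dataclass
class PairwiseComparison:
    """Agreement counts between two OTUs over the characters scored in both."""

    otu_a: str
    otu_b: str
    green: int
    yellow: int
    blue: int
    character_lists: dict[str, list[int]] = field(default_factory=dict)

    @property
    def overlap(self) -> int:
        return self.green + self.yellow + self.blue


@dataclass
class DelimitationResult:
    """Threshold classification of a pairwise difference count."""

    difference_count: float
    classification: str  # indistinct | species_level | genus_level
    thresholds: tuple[int, int] = (SPECIES_THRESHOLD, GENUS_THRESHOLD)
    degenerate: bool = False  # overlap was zero; classification unreliable


def compare_pair(
    matrix: CharacterMatrix,
    otu_a: str,
    otu_b: str,
    use_masks: bool = False,
) -> PairwiseComparison:
    """Categorize every character scored in both OTUs.

    By default all characters of the raw rows are considered; with
    ``use_masks`` inactive characters are excluded.
    """
    row_a = matrix.row(otu_a)
    row_b = matrix.row(otu_b)
    green = yellow = blue = 0
    lists: dict[str, list[int]] = {"green": [], "yellow": [], "blue": []}
    for j in range(matrix.n_characters):
        if use_masks and not matrix.active_characters[j]:
            continue
        ca, cb = row_a[j], row_b[j]
        if not (ca.is_scored and cb.is_scored):
            continue
        if ca.states == cb.states:
            green += 1
            lists["green"].append(j + 1)
        elif ca.states & cb.states:
            yellow += 1
            lists["yellow"].append(j + 1)
        else:
            blue += 1
            lists["blue"].append(j + 1)
    return PairwiseComparison(otu_a, otu_b, green, yellow, blue, lists)


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def difference_percent(
    comparison: PairwiseComparison, mode: str = "strict"
) -> tuple[float, float]:
    """Difference percentage of a comparison.

    ``strict`` counts only outright disagreements: 100 * blue / overlap.
    ``half_credit`` adds half a difference per partial agreement:
    100 * (blue + 0.5 * yellow) / overlap.

    Returns ``(reported, unrounded)`` where the reported value is rounded
    half-up to one decimal.
    """
    if comparison.overlap == 0:
        raise UndefinedPercentageError(
            f"{comparison.otu_a} vs {comparison.otu_b}: no overlapping "
            "scored characters; difference percentage undefined"
        )
    if mode == "strict":
        value = 100.0 * comparison.blue / comparison.overlap
    elif mode == "half_credit":
        value = 100.0 * (comparison.blue + 0.5 * comparison.yellow) / comparison.overlap
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _round_half_up(value, 1), value


def delimit(
    comparison: PairwiseComparison,
    basis: str = "blue",
    thresholds: tuple[int, int] = (SPECIES_THRESHOLD, GENUS_THRESHOLD),
) -> DelimitationResult:
    """Classify a pair as indistinct / species-level / genus-level.

    ``basis`` selects the difference count: ``blue`` (default) or
    ``blue_plus_half`` (blue + 0.5 * yellow).  Boundaries are inclusive:
    a count equal to the species threshold is a species-level separation.
    """
    if basis == "blue":
        count: float = comparison.blue
    elif basis == "blue_plus_half":
        count = comparison.blue + 0.5 * comparison.yellow
    else:
        raise ValueError(f"unknown basis {basis!r}")
    species_t, genus_t = thresholds
    if count >= genus_t:
        cls = "genus_level"
    elif count >= species_t:
        cls = "species_level"
    else:
        cls = "indistinct"
    return DelimitationResult(
        difference_count=count,
        classification=cls,
        thresholds=thresholds,
        degenerate=(comparison.overlap == 0),
    )


def pairwise_table(
    matrix: CharacterMatrix,
    focal_otus: Sequence[str],
    basis: str = "blue",
    thresholds: tuple[int, int] = (SPECIES_THRESHOLD, GENUS_THRESHOLD),
) -> list[dict]:
    """All unordered pairs among the focal OTUs, with counts, both
    percentage modes and the delimitation class.

    Returns a list of plain dict rows, ready for TSV/JSON serialization.
    """
    focal = list(focal_otus)
    if len(focal) < 2:
        raise ValueError("need at least two focal OTUs")
    rows = []
    for a, b in combinations(focal, 2):
        cmp = compare_pair(matrix, a, b)
        if cmp.overlap > 0:
            pct_strict = difference_percent(cmp, "strict")[0]
            pct_half = difference_percent(cmp, "half_credit")[0]
        else:
            pct_strict = pct_half = float("nan")
        res = delimit(cmp, basis=basis, thresholds=thresholds)
        rows.append(
            {
                "otu_a": a,
                "otu_b": b,
                "green": cmp.green,
                "yellow": cmp.yellow,
                "blue": cmp.blue,
                "overlap": cmp.overlap,
                "pct_strict": pct_strict,
                "pct_half": pct_half,
                "difference_count": res.difference_count,
                "class": res.classification,
                "degenerate": res.degenerate,
            }
        )
    return rows


def table_to_tsv(rows: Iterable[dict]) -> str:
    rows = list(rows)
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"


def table_to_json(rows: Iterable[dict]) -> str:
    return json.dumps(list(rows), indent=2)


def plot_agreement_bars(rows: Sequence[dict], focal: str, path: str) -> None:
    """Stacked horizontal bars of green/yellow/blue counts for one focal OTU
    against every partner in the table (overlap totals annotated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    partners, greens, yellows, blues = [], [], [], []
    for r in rows:
        if focal in (r["otu_a"], r["otu_b"]):
            partners.append(r["otu_b"] if r["otu_a"] == focal else r["otu_a"])
            greens.append(r["green"])
            yellows.append(r["yellow"])
            blues.append(r["blue"])
    fig, ax = plt.subplots(figsize=(8, 0.5 * max(4, len(partners))))
    y = range(len(partners))
    ax.barh(y, greens, color="#2ca02c", label="identical")
    ax.barh(y, yellows, left=greens, color="#ffdf00", label="partial")
    ax.barh(
        y,
        blues,
        left=[g + yl for g, yl in zip(greens, yellows)],
        color="#1f77b4",
        label="different",
    )
    for yi, (g, yl, b) in enumerate(zip(greens, yellows, blues)):
        ax.text(g + yl + b + 0.5, yi, f"[{g + yl + b}]", va="center", fontsize=8)
    ax.set_yticks(list(y))
    ax.set_yticklabels(partners, fontsize=8)
    ax.set_xlabel("characters scored in both OTUs")
    ax.set_title(f"Character agreement with {focal}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
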