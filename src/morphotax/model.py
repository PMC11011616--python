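"""Core data model for discrete morphological character matrices.

A matrix is a rectangular grid of :class:`CellScore` objects indexed by
OTU (operational taxonomic unit — a named species holotype or an
individual specimen treated as a terminal) and character.  Characters are
reported 1-based, following the ``C###`` convention of the palaeontological
literature; all internal indexing is 0-based.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CellScore",
    "CharacterMatrix",
    "ScorePatch",
    "AnalysisSettings",
    "MatrixError",
    "MatrixParseError",
    "DimensionMismatchError",
    "UnclosedBracketError",
    "DuplicateTaxonError",
    "IllegalSymbolError",
    "UnknownOTUError",
    "PatchMismatchError",
    "normalize_label",
]

# State symbols accepted in matrix files: 0-9 then A-V, i.e. up to 32 states.
STATE_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"
SYMBOL_TO_STATE = {s: i for i, s in enumerate(STATE_SYMBOLS)}


class MatrixError(Exception):
    """Base class for matrix-related errors."""


class MatrixParseError(MatrixError):
    """A malformed matrix file; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DimensionMismatchError(MatrixParseError):
    pass


class UnclosedBracketError(MatrixParseError):
    pass


class DuplicateTaxonError(MatrixParseError):
    pass


class IllegalSymbolError(MatrixParseError):
    pass


class UnknownOTUError(MatrixError):
    pass


class PatchMismatchError(MatrixError):
    """Strict patching found a cell that does not hold the recorded old score."""


def normalize_label(label: str) -> str:
    """Collapse internal whitespace/underscores so that ``Taxon name`` and
    ``Taxon_name`` compare equal (TNT files replace spaces with underscores)."""
    return re.sub(r"[\s_]+", "_", label.strip())


@dataclass(frozen=True)
class CellScore:
    """One matrix cell: a set of discrete states, or missing, or inapplicable.

    ``status`` is one of ``scored``, ``missing``, ``inapplicable``.  A scored
    cell with two or more states is polymorphic/uncertain (written ``[01]`` in
    TNT, ``{01}`` in NEXUS).  Missing (``?``) and inapplicable (``-``) are
    parsed distinctly but treated identically as "unscored" by downstream
    counting and optimization.
    """

    states: frozenset[int] = frozenset()
    status: str = "missing"

    def __post_init__(self):
        if self.status not in ("scored", "missing", "inapplicable"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "scored" and not self.states:
            raise ValueError("scored cell must have at least one state")
        if self.status != "scored" and self.states:
            raise ValueError("unscored cell must have an empty state set")
        object.__setattr__(self, "states", frozenset(self.states))

    @classmethod
    def scored(cls, *states: int) -> "CellScore":
        return cls(frozenset(states), "scored")

    @classmethod
    def missing(cls) -> "CellScore":
        return cls(frozenset(), "missing")

    @classmethod
    def inapplicable(cls) -> "CellScore":
        return cls(frozenset(), "inapplicable")

    @classmethod
    def from_text(cls, text: str) -> "CellScore":
        """Parse a single-cell token: ``1``, ``?``, ``-``, ``0&1``, ``[01]``, ``{01}``."""
        t = text.strip()
        if t == "?":
            return cls.missing()
        if t == "-":
            return cls.inapplicable()
        t = t.strip("[]{}")
        parts = t.split("&") if "&" in t else list(t)
        states = set()
        for p in parts:
            p = p.strip()
            if p not in SYMBOL_TO_STATE:
                raise ValueError(f"illegal state symbol {p!r} in {text!r}")
            states.add(SYMBOL_TO_STATE[p])
        if not states:
            raise ValueError(f"empty cell token {text!r}")
        return cls.scored(*states)

    @property
    def is_scored(self) -> bool:
        return self.status == "scored"

    @property
    def is_polymorphic(self) -> bool:
        return len(self.states) >= 2

    def to_text(self, style: str = "amp") -> str:
        """Render the cell: ``amp`` → ``0&1``, ``tnt`` → ``[01]``, ``nexus`` → ``{01}``."""
        if self.status == "missing":
            return "?"
        if self.status == "inapplicable":
            return "-"
        syms = "".join(STATE_SYMBOLS[s] for s in sorted(self.states))
        if len(syms) == 1:
            return syms
        if style == "tnt":
            return f"[{syms}]"
        if style == "nexus":
            return "{" + syms + "}"
        return "&".join(syms)

    def __str__(self):
        return self.to_text()


@dataclass
class CharacterMatrix:
    """OTU labels x characters grid of :class:`CellScore` with per-character
    ordering flags and active/inactive masks.

    Ordered (additive) characters cost ``|i - j|`` steps per change; unordered
    characters cost one step between any two states.  Masks record a-priori
    exclusions without losing the underlying rows.
    """

    otu_labels: list[str]
    n_characters: int
    cells: list[list[CellScore]]
    ordered_flags: list[bool] = field(default_factory=list)
    active_otus: list[bool] = field(default_factory=list)
    active_characters: list[bool] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.otu_labels)
        if len({normalize_label(l) for l in self.otu_labels}) != n:
            raise DuplicateTaxonError("duplicate OTU labels after normalization")
        if len(self.cells) != n:
            raise DimensionMismatchError(
                f"{len(self.cells)} rows for {n} OTU labels"
            )
        for i, row in enumerate(self.cells):
            if len(row) != self.n_characters:
                raise DimensionMismatchError(
                    f"OTU {self.otu_labels[i]!r} has {len(row)} cells, "
                    f"expected {self.n_characters}"
                )
        if not self.ordered_flags:
            self.ordered_flags = [False] * self.n_characters
        if not self.active_otus:
            self.active_otus = [True] * n
        if not self.active_characters:
            self.active_characters = [True] * self.n_characters

    # -- basic accessors -------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_labels)

    def otu_index(self, label: str) -> int:
        key = normalize_label(label)
        for i, l in enumerate(self.otu_labels):
            if normalize_label(l) == key:
                return i
        raise UnknownOTUError(f"unknown OTU {label!r}")

    def row(self, label: str) -> list[CellScore]:
        return self.cells[self.otu_index(label)]

    def cell(self, label: str, character: int) -> CellScore:
        """Cell for OTU ``label`` at 1-based character index."""
        self._check_char(character)
        return self.cells[self.otu_index(label)][character - 1]

    def _check_char(self, character: int):
        if not 1 <= character <= self.n_characters:
            raise IndexError(
                f"character {character} outside 1..{self.n_characters}"
            )

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.otu_labels),
            self.n_characters,
            [list(r) for r in self.cells],
            list(self.ordered_flags),
            list(self.active_otus),
            list(self.active_characters),
        )

    # -- views -----------------------------------------------------------
    def active_otu_labels(self) -> list[str]:
        return [l for l, a in zip(self.otu_labels, self.active_otus) if a]

    def active_submatrix(self) -> "CharacterMatrix":
        """Matrix restricted to active OTUs and active characters."""
        keep_c = [j for j in range(self.n_characters) if self.active_characters[j]]
        labels = self.active_otu_labels()
        cells = [
            [self.cells[i][j] for j in keep_c]
            for i in range(self.n_otus)
            if self.active_otus[i]
        ]
        return CharacterMatrix(
            labels,
            len(keep_c),
            cells,
            [self.ordered_flags[j] for j in keep_c],
        )

    def status_counts(self) -> dict[str, int]:
        counts = {"scored": 0, "missing": 0, "inapplicable": 0}
        for row in self.cells:
            for c in row:
                counts[c.status] += 1
        return counts

    def __eq__(self, other):
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.otu_labels == other.otu_labels
            and self.n_characters == other.n_characters
            and self.cells == other.cells
            and self.ordered_flags == other.ordered_flags
            and self.active_otus == other.active_otus
            and self.active_characters == other.active_characters
        )


@dataclass(frozen=True)
class ScorePatch:
    """One recorded score change: ``C<character> (old -> new)`` for one OTU."""

    otu: str
    character: int  # 1-based
    old: CellScore
    new: CellScore

    def __post_init__(self):
        if self.old == self.new:
            raise ValueError("patch old and new scores are identical")


@dataclass
class AnalysisSettings:
    """Configuration applied before scoring: character ordering, a-priori OTU
    exclusions, and the weighting scheme.

    ``k`` is the implied-weighting concavity constant (character fit
    ``h/(h+k)``); larger k is more lenient toward homoplasy.
    ``missing_downweight`` enables harsher downweighting of characters with
    many missing entries under extended implied weighting.
    """

    ordered_characters: list[int] = field(default_factory=list)  # 1-based
    excluded_otus: list[str] = field(default_factory=list)
    weighting: str = "equal"  # equal | implied | extended_implied
    k: float = 9.0
    missing_downweight: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.weighting not in ("equal", "implied", "extended_implied"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.k <= 0:
            raise ValueError("k must be positive")


def apply_patches(
    matrix: CharacterMatrix,
    patches: Sequence[ScorePatch],
    strict: bool = True,
) -> tuple[CharacterMatrix, list[str]]:
    """Apply recorded score changes, returning a new matrix and a change log.

    In strict mode each patch's recorded old score must equal the current
    cell, guarding against applying a change list to the wrong matrix
    version.  Patches targeting distinct cells commute.
    """
    out = matrix.copy()
    log: list[str] = []
    for p in patches:
        i = out.otu_index(p.otu)  # raises UnknownOTUError
        out._check_char(p.character)
        j = p.character - 1
        current = out.cells[i][j]
        if strict and current != p.old:
            raise PatchMismatchError(
                f"{p.otu} C{p.character}: recorded old score "
                f"{p.old} but matrix holds {current}"
            )
        out.cells[i][j] = p.new
        log.append(f"{out.otu_labels[i]} C{p.character}: {current} -> {p.new}")
    return out, log


def configure(matrix: CharacterMatrix, settings: AnalysisSettings) -> CharacterMatrix:
    """Return a matrix with ordering flags set and excluded OTUs deactivated."""
    out = matrix.copy()
    out.ordered_flags = [False] * out.n_characters
    for c in settings.ordered_characters:
        out._check_char(c)
        out.ordered_flags[c - 1] = True
    for name in settings.excluded_otus:
        out.active_otus[out.otu_index(name)] = False
    return out


# The eighteen ordered (additive) characters of the Winton Formation
# sauropod matrix, 1-based.
ORDERED_CHARACTERS_DEFAULT = [
    11, 14, 15, 27, 40, 51, 104, 122, 147, 148,
    195, 205, 259, 297, 426, 435, 472, 510,
]

# Eight taxa excluded a priori from every analysis of that matrix...
EXCLUDED_ALWAYS = [
    "Astrophocaudia slaughteri",
    "Australodocus bohetii",
    "Brontomerus mcintoshi",
    "Fukuititan nipponensis",
    "Fusuisaurus zhaoi",
    "Liubangosaurus hei",
    "Malarguesaurus florenciae",
    "Mongolosaurus haplodon",
]

# ...and two more excluded only under equal character weighting.
EXCLUDED_EQUAL_WEIGHTS_ONLY = [
    "Cloverly titanosauriform",
    "Ruyangosaurus giganteus",
]


def default_settings(weighting: str = "equal", seed: int | None = None) -> AnalysisSettings:
    """The published analysis protocol for the Winton sauropod matrix."""
    excluded = list(EXCLUDED_ALWAYS)
    if weighting == "equal":
        excluded += EXCLUDED_EQUAL_WEIGHTS_ONLY
    return AnalysisSettings(
        ordered_characters=list(ORDERED_CHARACTERS_DEFAULT),
        excluded_otus=excluded,
        weighting=weighting,
        k=9.0,
        missing_downweight=(weighting == "extended_implied"),
        seed=seed,
    )
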