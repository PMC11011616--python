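"""Reading and writing character matrices (TNT xread, NEXUS), patch lists
and analysis settings.

The TNT ``xread`` dialect has no parser in the standard Python stack, so it
is implemented here; NEXUS CHARACTERS/DATA blocks are parsed through
dendropy and converted to :class:`~morphotax.model.CharacterMatrix`.
"""

from __future__ import annotations

import io as _io
import re
from typing import Iterable, TextIO

import dendropy

from .model import (
    STATE_SYMBOLS,
    SYMBOL_TO_STATE,
    AnalysisSettings,
    CellScore,
    CharacterMatrix,
    DimensionMismatchError,
    DuplicateTaxonError,
    IllegalSymbolError,
    MatrixParseError,
    ScorePatch,
    UnclosedBracketError,
    normalize_label,
)

__all__ = [
    "read_tnt",
    "write_tnt",
    "read_nexus",
    "write_nexus",
    "read_patches",
    "write_patches",
    "read_settings",
    "write_settings",
]


def _as_stream(source) -> TextIO:
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# TNT xread
# ---------------------------------------------------------------------------

def _parse_symbol_row(row: str, line_no: int) -> list[CellScore]:
    """Parse a contiguous TNT/NEXUS symbol string into cells."""
    cells: list[CellScore] = []
    i = 0
    n = len(row)
    while i < n:
        ch = row[i]
        if ch in "[{":
            close = "]" if ch == "[" else "}"
            j = row.find(close, i + 1)
            if j < 0:
                raise UnclosedBracketError(
                    f"unclosed {ch!r} in row {row!r}", line=line_no
                )
            group = row[i + 1 : j]
            states = set()
            for s in group:
                if s not in SYMBOL_TO_STATE:
                    raise IllegalSymbolError(
                        f"illegal state symbol {s!r} inside brackets", line=line_no
                    )
                states.add(SYMBOL_TO_STATE[s])
            if not states:
                raise IllegalSymbolError("empty bracket group", line=line_no)
            cells.append(CellScore.scored(*states))
            i = j + 1
        elif ch == "?":
            cells.append(CellScore.missing())
            i += 1
        elif ch == "-":
            cells.append(CellScore.inapplicable())
            i += 1
        elif ch in SYMBOL_TO_STATE:
            cells.append(CellScore.scored(SYMBOL_TO_STATE[ch]))
            i += 1
        elif ch in "]}":
            raise UnclosedBracketError(
                f"unmatched {ch!r} in row {row!r}", line=line_no
            )
        else:
            raise IllegalSymbolError(
                f"illegal symbol {ch!r} in row {row!r}", line=line_no
            )
    return cells


def read_tnt(source) -> CharacterMatrix:
    """Parse a TNT ``xread`` block into a :class:`CharacterMatrix`.

    Accepts the common dialect: optional quoted title after ``xread``, a
    counts line giving *nchar* then *ntax*, then taxon rows (name followed by
    a contiguous symbol string, possibly split across several lines), with an
    optional terminating ``;``.  Symbols 0-9 and A-V are states, ``?`` is
    missing, ``-`` inapplicable, ``[..]`` polymorphism.
    """
    text = _as_stream(source).read()
    m = re.search(r"\bxread\b", text, flags=re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread block found", line=1)
    rest = text[m.end():]
    # optional quoted title
    rest = re.sub(r"^\s*'[^']*'", "", rest, count=1)
    offset = len(text) - len(rest)
    start_line = text.count("\n", 0, offset) + 1

    # Everything up to the terminating ';' (if present).
    body = rest.split(";")[0]

    tokens = body.split()
    if len(tokens) < 2:
        raise MatrixParseError("missing counts line after xread", line=start_line)
    try:
        nchar = int(tokens[0])
        ntax = int(tokens[1])
    except ValueError:
        raise MatrixParseError(
            f"counts line must be 'nchar ntax', got {tokens[0]!r} {tokens[1]!r}",
            line=start_line,
        )

    # Consume the counts tokens, then read the remaining tokens pairwise:
    # taxon name followed by one contiguous symbol string.  Each token
    # carries its source line for error reporting.
    tok_with_lines: list[tuple[str, int]] = []
    for k, raw in enumerate(body.split("\n")):
        for t in raw.split():
            tok_with_lines.append((t, start_line + k))
    # skip the two counts tokens
    tok_with_lines = tok_with_lines[2:]

    if len(tok_with_lines) % 2 != 0:
        raise MatrixParseError(
            "taxon rows must be 'name symbols' pairs",
            line=tok_with_lines[-1][1] if tok_with_lines else start_line,
        )

    labels: list[str] = []
    cells: list[list[CellScore]] = []
    seen_norm: set[str] = set()
    for (name, name_line), (symbols, sym_line) in zip(
        tok_with_lines[0::2], tok_with_lines[1::2]
    ):
        key = normalize_label(name)
        if key in seen_norm:
            raise DuplicateTaxonError(
                f"duplicate taxon name {name!r}", line=name_line
            )
        row = _parse_symbol_row(symbols, sym_line)
        if len(row) != nchar:
            raise DimensionMismatchError(
                f"taxon {name!r} has {len(row)} characters, expected {nchar}",
                line=sym_line,
            )
        seen_norm.add(key)
        labels.append(name)
        cells.append(row)

    if len(labels) != ntax:
        raise DimensionMismatchError(
            f"counts line declares {ntax} taxa but {len(labels)} rows found",
            line=start_line,
        )
    return CharacterMatrix(labels, nchar, cells)


def write_tnt(matrix: CharacterMatrix, title: str = "") -> str:
    """Serialize a matrix as a TNT ``xread`` block."""
    out = ["xread"]
    if title:
        out[0] += f" '{title}'"
    out.append(f"{matrix.n_characters} {matrix.n_otus}")
    width = max(len(normalize_label(l)) for l in matrix.otu_labels) + 2
    for label, row in zip(matrix.otu_labels, matrix.cells):
        sym = "".join(c.to_text("tnt") for c in row)
        out.append(f"{normalize_label(label):<{width}}{sym}")
    out.append(";")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# NEXUS (via dendropy)
# ---------------------------------------------------------------------------

def read_nexus(source) -> CharacterMatrix:
    """Parse a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`."""
    text = _as_stream(source).read()
    if not re.search(r"\bNCHAR\s*=", text, flags=re.IGNORECASE):
        raise DimensionMismatchError("NEXUS DIMENSIONS lacks NCHAR")
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as e:  # dendropy raises schema-specific errors
        raise MatrixParseError(f"NEXUS parse failed: {e}") from None

    labels: list[str] = []
    cells: list[list[CellScore]] = []
    nchar = None
    for taxon in dmat:
        row = []
        for state in dmat[taxon]:
            sym = state.symbol
            if sym == "?":
                row.append(CellScore.missing())
            elif sym == "-":
                row.append(CellScore.inapplicable())
            elif state.member_states:  # polymorphic / uncertain set
                states = set()
                for member in state.member_states:
                    ms = member.symbol
                    if ms in ("?", "-"):
                        continue
                    if ms not in SYMBOL_TO_STATE:
                        raise IllegalSymbolError(f"undeclared symbol {ms!r}")
                    states.add(SYMBOL_TO_STATE[ms])
                if states:
                    row.append(CellScore.scored(*states))
                else:
                    row.append(CellScore.missing())
            else:
                if sym not in SYMBOL_TO_STATE:
                    raise IllegalSymbolError(f"undeclared symbol {sym!r}")
                row.append(CellScore.scored(SYMBOL_TO_STATE[sym]))
        if nchar is None:
            nchar = len(row)
        labels.append(taxon.label)
        cells.append(row)
    if nchar is None:
        raise MatrixParseError("NEXUS file contains no character rows")
    return CharacterMatrix(labels, nchar, cells)


def write_nexus(matrix: CharacterMatrix, title: str = "") -> str:
    """Serialize a matrix as a NEXUS DATA block (braces for polymorphism)."""
    max_state = 0
    for row in matrix.cells:
        for c in row:
            if c.states:
                max_state = max(max_state, max(c.states))
    symbols = STATE_SYMBOLS[: max_state + 1]
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_otus} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    width = max(len(normalize_label(l)) for l in matrix.otu_labels) + 2
    for label, row in zip(matrix.otu_labels, matrix.cells):
        sym = "".join(c.to_text("nexus") for c in row)
        lines.append(f"{normalize_label(label):<{width}}{sym}")
    lines += [";", "END;"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Patch lists (TSV: otu, character, old, new) and settings
# ---------------------------------------------------------------------------

def read_patches(source) -> list[ScorePatch]:
    """Read a patch TSV with columns otu, character (1-based), old, new.

    Cell tokens use the in-text convention: ``0``, ``?``, ``-``, ``0&1``.
    """
    stream = _as_stream(source)
    patches = []
    for i, raw in enumerate(stream.read().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "otu":  # header
            continue
        if len(parts) != 4:
            raise MatrixParseError(
                f"patch row needs 4 tab-separated fields, got {len(parts)}",
                line=i,
            )
        otu, char_s, old_s, new_s = parts
        patches.append(
            ScorePatch(
                otu=otu,
                character=int(char_s),
                old=CellScore.from_text(old_s),
                new=CellScore.from_text(new_s),
            )
        )
    return patches


def write_patches(patches: Iterable[ScorePatch]) -> str:
    lines = ["otu\tcharacter\told\tnew"]
    for p in patches:
        lines.append(f"{p.otu}\t{p.character}\t{p.old}\t{p.new}")
    return "\n".join(lines) + "\n"


def read_settings(source) -> AnalysisSettings:
    """Read a plain-text key=value settings file.

    Keys: ordered_characters (comma-separated 1-based indices),
    excluded_otus (comma-separated names), weighting, k,
    missing_downweight (true/false), seed.
    """
    stream = _as_stream(source)
    kv: dict[str, str] = {}
    for raw in stream.read().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise MatrixParseError(f"settings line lacks '=': {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    settings = AnalysisSettings()
    if "ordered_characters" in kv and kv["ordered_characters"]:
        settings.ordered_characters = [
            int(x) for x in kv["ordered_characters"].split(",")
        ]
    if "excluded_otus" in kv and kv["excluded_otus"]:
        settings.excluded_otus = [x.strip() for x in kv["excluded_otus"].split(",")]
    if "weighting" in kv:
        settings.weighting = kv["weighting"]
    if "k" in kv:
        settings.k = float(kv["k"])
    if "missing_downweight" in kv:
        settings.missing_downweight = kv["missing_downweight"].lower() in (
            "1", "true", "yes",
        )
    if "seed" in kv and kv["seed"]:
        settings.seed = int(kv["seed"])
    settings.__post_init__()  # re-validate
    return settings


def write_settings(settings: AnalysisSettings) -> str:
    lines = [
        "ordered_characters=" + ",".join(str(c) for c in settings.ordered_characters),
        "excluded_otus=" + ",".join(settings.excluded_otus),
        f"weighting={settings.weighting}",
        f"k={settings.k}",
        f"missing_downweight={'true' if settings.missing_downweight else 'false'}",
        f"seed={'' if settings.seed is None else settings.seed}",
    ]
    return "\n".join(lines) + "\n"
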