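"""Autapomorphy audits and vertebral morphometrics.

An audit crosses a list of diagnostic characters (each tied to the taxon
it diagnoses and to the anatomical elements needed to assess it) with the
elements each specimen preserves, producing the familiar O / X / – table:
O the specimen possesses the feature, X it demonstrably lacks it, – it
cannot be assessed because the relevant element is not preserved.

The audit feeds a rule-based referral suggestion, and the module also
computes the average Elongation Index of caudal vertebral centra,

    aEI = L / ((W + H) / 2),

with L the anteroposterior centrum length excluding the articular ball
and W, H the mediolateral width and dorsoventral height of the posterior
articular surface (all in mm), plus simple limb-proportion ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DiagnosticCharacter",
    "SpecimenRecord",
    "VertebraMeasurement",
    "AuditError",
    "audit",
    "suggest_referral",
    "aei",
    "limb_ratio",
    "load_bundled_diagnostics",
    "load_bundled_specimens",
]


class AuditError(Exception):
    pass


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A proposed diagnostic feature of one taxon.

    ``status`` is ``autapomorphy`` (unique to the taxon),
    ``local_autapomorphy`` (unique within a region of the tree but
    convergent elsewhere in the clade) or ``synapomorphy_candidate``
    (better interpreted as diagnosing the containing clade, not the taxon).
    """

    id: str
    taxon: str
    status: str
    required_elements: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if self.status not in (
            "autapomorphy",
            "local_autapomorphy",
            "synapomorphy_candidate",
        ):
            raise ValueError(f"bad status {self.status!r}")
        if not self.required_elements:
            raise ValueError("required_elements must be non-empty")


@dataclass
class SpecimenRecord:
    """A specimen, the anatomical elements it preserves, and its recorded
    assessments (diagnostic id -> possesses / lacks / unassessable)."""

    id: str
    preserved_elements: frozenset[str]
    assessments: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class VertebraMeasurement:
    """Centrum measurements of one caudal vertebra, in mm.  ``incomplete``
    marks a measurement taken from an incompletely preserved element."""

    specimen: str
    element: str
    length: float
    width: float
    height: float
    incomplete: bool = False

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("measurements must be positive")


SYMBOL = {"possesses": "O", "lacks": "X", "unassessable": "-"}


def audit(
    specimens: Sequence[SpecimenRecord],
    diagnostics: Sequence[DiagnosticCharacter],
) -> dict:
    """Cross specimens with diagnostics into an O/X/– table.

    Validates that every possesses/lacks assessment is actually assessable
    given the preserved elements; an inconsistent cell raises
    :class:`AuditError` naming it.  Returns the symbol table plus per-taxon
    tallies (possessed / lacked / assessable counts per specimen).
    """
    table: dict[str, dict[str, str]] = {}
    for sp in specimens:
        row: dict[str, str] = {}
        for d in diagnostics:
            a = sp.assessments.get(d.id, "unassessable")
            if a not in SYMBOL:
                raise AuditError(f"{sp.id} / {d.id}: bad assessment {a!r}")
            if a != "unassessable" and not d.required_elements <= sp.preserved_elements:
                missing = sorted(d.required_elements - sp.preserved_elements)
                raise AuditError(
                    f"{sp.id} / {d.id}: assessment {a!r} recorded but "
                    f"required element(s) {missing} not preserved"
                )
            row[d.id] = SYMBOL[a]
        table[sp.id] = row

    tallies: dict[str, dict[str, dict[str, int]]] = {}
    for sp in specimens:
        tallies[sp.id] = {}
        for d in diagnostics:
            t = tallies[sp.id].setdefault(
                d.taxon, {"possessed": 0, "lacked": 0, "assessable": 0}
            )
            sym = table[sp.id][d.id]
            if sym != "-":
                t["assessable"] += 1
                t["possessed" if sym == "O" else "lacked"] += 1
    return {"symbols": table, "tallies": tallies}


def suggest_referral(
    specimen: SpecimenRecord,
    diagnostics: Sequence[DiagnosticCharacter],
    clade_name: str = "Diamantinasauria",
) -> dict:
    """Rule-based referral suggestion from one specimen's assessments.

    Default policy (data, not dogma — override by editing the diagnostics
    table): refer to taxon T when the specimen possesses at least one
    autapomorphy of T, possesses no autapomorphy of any other taxon, and
    lacks none of T's assessable autapomorphies.  Specimens whose only
    derived features are clade-level synapomorphy candidates are referred
    to the clade (indet.); conflicting evidence yields incertae sedis.
    """
    possessed_by_taxon: dict[str, list[str]] = {}
    lacked_by_taxon: dict[str, list[str]] = {}
    clade_evidence: list[str] = []
    for d in sorted(diagnostics, key=lambda d: d.id):  # order-insensitive
        a = specimen.assessments.get(d.id, "unassessable")
        if a == "unassessable":
            continue
        if d.status == "synapomorphy_candidate":
            if a == "possesses":
                clade_evidence.append(d.id)
            continue
        if a == "possesses":
            possessed_by_taxon.setdefault(d.taxon, []).append(d.id)
        else:
            lacked_by_taxon.setdefault(d.taxon, []).append(d.id)

    taxa_with_evidence = sorted(possessed_by_taxon)
    if len(taxa_with_evidence) > 1:
        return {
            "referred_to": "incertae_sedis",
            "rationale": (
                "possesses autapomorphies of more than one taxon: "
                + ", ".join(taxa_with_evidence)
            ),
        }
    if len(taxa_with_evidence) == 1:
        taxon = taxa_with_evidence[0]
        if taxon in lacked_by_taxon:
            return {
                "referred_to": "incertae_sedis",
                "rationale": (
                    f"possesses {len(possessed_by_taxon[taxon])} but lacks "
                    f"{len(lacked_by_taxon[taxon])} autapomorphies of {taxon}"
                ),
            }
        return {
            "referred_to": taxon,
            "rationale": (
                f"possesses autapomorph{'ies' if len(possessed_by_taxon[taxon]) > 1 else 'y'} "
                + ", ".join(possessed_by_taxon[taxon])
                + " and conflicts with no other taxon (tentative)"
            ),
        }
    if clade_evidence:
        return {
            "referred_to": f"{clade_name} indet.",
            "rationale": (
                "only clade-level synapomorphy candidates possessed: "
                + ", ".join(clade_evidence)
            ),
        }
    return {
        "referred_to": "incertae_sedis",
        "rationale": "no diagnostic feature possessed",
    }


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 2) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def aei(measurement: VertebraMeasurement) -> dict:
    """Average Elongation Index of a caudal centrum: L / ((W + H) / 2).

    Scale-invariant; reported half-up to two decimals, with the
    incompleteness flag propagated (an index from an incomplete element is
    conventionally printed with an asterisk).
    """
    value = measurement.length / ((measurement.width + measurement.height) / 2.0)
    return {
        "specimen": measurement.specimen,
        "element": measurement.element,
        "aei": _round_half_up(value, 2),
        "aei_unrounded": value,
        "incomplete": measurement.incomplete,
    }


def limb_ratio(numerator_length: float, denominator_length: float) -> float:
    """Proportion of one limb element to another (e.g. tibia/femur),
    reported half-up to two decimals."""
    if numerator_length <= 0 or denominator_length <= 0:
        raise ValueError("lengths must be positive")
    return _round_half_up(numerator_length / denominator_length, 2)


# ---------------------------------------------------------------------------
# Bundled fixtures: the published Winton Formation sauropod audit
# ---------------------------------------------------------------------------

def _read_data_tsv(name: str) -> list[list[str]]:
    text = resources.files("morphotax.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_bundled_diagnostics() -> list[DiagnosticCharacter]:
    """The published list of proposed postcranial autapomorphies of the
    four Winton Formation sauropod species (plus the ulnar interosseous
    ridge, reinterpreted as a clade synapomorphy candidate)."""
    rows = _read_data_tsv("diagnostics.tsv")
    header, body = rows[0], rows[1:]
    out = []
    for r in body:
        rec = dict(zip(header, r))
        out.append(
            DiagnosticCharacter(
                id=rec["id"],
                taxon=rec["taxon"],
                status=rec["status"],
                required_elements=frozenset(rec["required_elements"].split(",")),
                description=rec.get("description", ""),
            )
        )
    return out


def load_bundled_specimens() -> list[SpecimenRecord]:
    """The published audit grid: which diagnostic features each Winton
    Formation specimen possesses, lacks, or cannot be assessed for.

    Preserved-element sets are inferred from the assessable cells of the
    published table (a specimen assessed for a feature must preserve the
    elements that feature requires)."""
    diagnostics = {d.id: d for d in load_bundled_diagnostics()}
    rows = _read_data_tsv("audit_grid.tsv")
    header, body = rows[0], rows[1:]
    specimen_ids = header[1:]
    assessments: dict[str, dict[str, str]] = {s: {} for s in specimen_ids}
    for r in body:
        diag_id = r[0]
        for sp, sym in zip(specimen_ids, r[1:]):
            if sym == "O":
                assessments[sp][diag_id] = "possesses"
            elif sym == "X":
                assessments[sp][diag_id] = "lacks"
    out = []
    for sp in specimen_ids:
        preserved: set[str] = set()
        for diag_id in assessments[sp]:
            preserved |= diagnostics[diag_id].required_elements
        out.append(
            SpecimenRecord(
                id=sp,
                preserved_elements=frozenset(preserved),
                assessments=assessments[sp],
            )
        )
    return out
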