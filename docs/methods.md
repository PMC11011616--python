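# Methods

## The problem this package addresses

Specimen-level morphological taxonomy asks two linked questions: where do
individual fossil specimens fall on a phylogeny estimated under maximum
parsimony, and do the character-score differences between name-bearing
specimens justify separate species or genera? The package implements the
full chain — matrix curation, agreement counting, parsimony analysis,
autapomorphy audit, and simple morphometrics — with every stage testable
on synthetic data with known ground truth.

## Matrix model

A matrix cell is a set of discrete states, or missing (`?`), or
inapplicable (`-`). Missing and inapplicable are parsed distinctly but
treated identically as "unscored" everywhere downstream (agreement
counting and parsimony): matrix formats record the distinction, but the
analyses here draw none, matching the default treatment in standard
parsimony software. Polymorphic and uncertain scores are likewise merged
into a plain state set, because `[01]`/`{01}` notation does not encode
the difference. Characters are 1-based externally (the `C###` convention
of the descriptive literature) and 0-based internally. Taxon names match
after collapsing runs of whitespace/underscores, since TNT files replace
spaces with underscores.

Score patches record (OTU, character, old, new). In strict mode the old
score must equal the current cell — this catches the common error of
applying a change list to the wrong matrix version. Patches on distinct
cells commute.

The TNT `xread` dialect accepted is: optional quoted title, a counts
line (`nchar ntax`), then name/symbol-string token pairs, with states
`0-9A-V`, `?`, `-` and `[..]` polymorphism; rows may share a line but a
symbol string may not be split across tokens. NEXUS CHARACTERS/DATA
blocks are parsed via dendropy and converted; writing produces a plain
DATA block with braces for polymorphism. Write∘read is the identity on
well-formed files (property-tested on fuzzed matrices).

## Agreement statistic and delimitation

For OTUs A and B, every character scored in both contributes to exactly
one of: green (equal state sets), yellow (intersecting but unequal),
blue (disjoint). Yellow generalizes the illustrated "half overlap" case
(`0` vs `0&1`) to any intersecting-but-unequal pair such as `{0,1}` vs
`{1,2}`; the illustrated case is subsumed and no other rule is implied
by the source material. By default all characters of the raw rows are
counted (no masking), since the published counts appear to predate the
analysis exclusions.

Difference percentages: strict = 100·blue/overlap; half-credit =
100·(blue + yellow/2)/overlap. Reported values are rounded half-up to
one decimal; the unrounded value is kept. The delimitation rule
classifies a difference count (default basis: blue only) with inclusive
thresholds: ≥ 13 genus-level, ≥ 6 species-level, else indistinct. Blue
alone is the default basis because the published percentages that are
internally consistent (3/55 = 5.5%, 2/23 = 8.7%) match blue/overlap
exactly; two published percentages (16.9% for 15/106, 18.9% for 10/65)
match neither mode and are treated as irreproducible as printed. A pair
with zero overlap raises for percentages and is flagged `degenerate` in
delimitation.

## Parsimony

**Length.** Unordered characters are scored by Fitch state-set dynamic
programming (intersection where possible, otherwise union and one step);
ordered characters by Farris interval dynamic programming (interval
intersection where possible, otherwise the gap between intervals is
added). Both are vectorized across characters (bitmask arrays for
unordered, lo/hi integer arrays for ordered). Leaf assignments:
polymorphic cells contribute their state set (ordered: the closed
interval spanning their states) at zero forced cost; unscored cells
contribute the full observed alphabet (ordered: full observed range).
The tree is rooted arbitrarily at a leaf edge; length is root-invariant,
which the tests verify, and equals the brute-force minimum over all
internal-state assignments on every fuzz case tried. Polytomous input is
rejected for length unless a flag requests the brute-force minimum over
binary resolutions (small trees only).

**Per-character bounds.** m (best case on any tree): unordered — the
smallest number of states hitting every scored cell's set, minus one
(exhaustive over subsets of the tiny observed alphabet); ordered — the
minimal spanned range after committing each polymorphic cell, i.e.
max(0, max(lo) − min(hi)). g (the completely unresolved bush): unordered
— scored cells minus the best single-state hit count; ordered — the
best-median sum of distances to each cell's interval. CI = Σm/L and
RI = (Σg − L)/(Σg − Σm) are computed over all characters by default
(standard software includes uninformative characters); an
`informative_only` flag restricts to characters with m < g. Degenerate
cases are guarded: CI is NaN at L = 0, RI is NaN when Σg = Σm.

**Implied weighting.** Fit = Σ h_i/(h_i + k_i), h_i = s_i − m_i, lower
is better; default k = 9. Standard mode uses a single k. The extended
variant (downweighting missing-rich characters faster) has no published
closed form, so it is implemented as a documented monotone map
k_i = max(k_min, k·(1 − f_i)) with f_i the character's unscored fraction
among active OTUs and k_min = 0.1; more missing data ⇒ smaller k_i ⇒
harsher downweighting. Because the exact map is this package's own
convention, extended-mode scores are comparable within an analysis but
not to other software's extended scores.

**Search.** Exhaustive enumeration by stepwise addition is available to
9 taxa ((2n−5)!! topologies) and returns every optimum. The heuristic is
random-addition greedy insertion followed by first-improvement
tree-bisection–reconnection hill climbing; all equally optimal trees
encountered are retained (first-found order, default cap 10 000), and a
seed is mandatory. On every ≤ 9-taxon fuzz case in the suite the
heuristic equals the exhaustive optimum. Zero-length branches are not
collapsed.

**Consensus and Bremer.** Strict consensus intersects bipartition sets
and rebuilds the (possibly polytomous) tree; it is cross-checked against
dendropy's strict consensus in the tests. Bremer support for a
consensus clade is the smallest extra length d at which the clade drops
out of the strict consensus of all trees within optimum + d. With ≤ 9
taxa the tree pool is the complete enumeration and values are exact;
above that a relaxed-retention TBR sweep builds the pool and values are
upper bounds dependent on search effort — exact decay values on large
matrices are search-strategy-dependent and are not claimed.

## Audit and morphometrics

Diagnostics (id, taxon, status, required anatomical elements) and the
published audit grid ship as editable TSV fixtures rather than code,
because the diagnostic list is revisable scholarship. A specimen's
preserved-element set is inferred from the assessable cells of the
published table; `audit()` re-validates that every O/X cell is
assessable and raises on inconsistencies. One cell of the published grid
is blank in the source table (the Savannasaurus hourglass metacarpal IV
column for AODF 2296); it is encoded as X, following the accompanying
text, which states the specimen lacks that feature.

The referral rule is an explicit default policy codifying the narrative
practice, not a claim about any author's reasoning: refer to taxon T iff
the specimen possesses ≥ 1 autapomorphy (or local autapomorphy) of T,
possesses none of any other taxon, and lacks none of T's assessable
autapomorphies; specimens whose only derived features are clade-level
synapomorphy candidates go to the clade as indet.; conflicts yield
incertae sedis. It reproduces the published outcome for the clear-cut
specimens and is deliberately stricter than expert judgement for
borderline ones (e.g. a specimen possessing two tibial autapomorphies
but lacking a third on a damaged surface stays in open nomenclature).

aEI = L/((W + H)/2) with L the centrum length excluding the articular
ball and W, H the posterior articular surface width and height; values
and limb ratios are rounded half-up to two decimals, matching the
presentation convention of the descriptive literature, and the
incomplete-element flag (the table asterisk) is propagated.

## Synthetic data

The generator emulates the target data regime: 131 OTUs × 560 characters
with roughly half the cells unscored is the headline scale, and the
acceptance script uses exactly that; tests use smaller instances of the
same process. Characters evolve independently along a random (or given)
tree under a symmetric k-state change process: changes per branch are
Poisson with mean equal to the branch length (expected changes per
character), each change picking a uniform different state, or ±1 with
reflection for ordered characters. Missingness is uniform at random by
default, with an element-block mode that deletes contiguous character
ranges per OTU to emulate element-wise fossil preservation. Polymorphism
adds one adjacent/random state at a configurable rate. A separate
noise-free mode generates clean binary split characters cycling over the
true tree's internal edges, guaranteeing the generating tree is the
unique most parsimonious tree with CI = RI = 1 — the sharpest possible
recovery oracle. Planted pairs append an OTU built cell-by-cell to hit
exact green/yellow/blue counts against a base OTU, with all other cells
missing. All outputs are byte-identical for a given seed.

What the simulations do not model: correlated characters and
morphological integration, phylogenetically clumped missingness beyond
the block mode, state-frequency asymmetries, and scoring error. Passing
recovery tests therefore demonstrate correctness of the algorithms under
the stated generative model, not robustness to every property of real
fossil matrices.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen as the package's
own verification scale: 5–9-taxon matrices wherever an exhaustive or
brute-force oracle is the comparator (945–10 395 topologies), 100 seeds
for planted-pair recovery, and the full 131 × 560 scale only for linear
-time operations (generation, serialization, agreement counting). Full
-matrix tree search is supported but is a long-running operation by
nature; its published optimum is checked only when the published matrix
file is supplied externally. Floating-point score comparisons in search
use an absolute tolerance of 1e-12; lengths and step counts are exact
integers throughout.

## Known limitations

* The extended implied-weighting map is a package convention (see
  above); published extended-weighting scores are not reproducible from
  it and are not claimed.
* Bremer values above the exhaustive cap depend on search effort and are
  upper bounds.
* The TNT dialect reader covers `xread`/`tread` as typically exported
  for matrices of this kind, not TNT command scripts, step matrices, or
  per-character weights beyond ordering flags.
* Published difference percentages that are inconsistent with their own
  printed counts (see the agreement section) are not reproduced by
  either implemented mode.
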