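# Methods notes

This note records the scientific conventions, parameter choices and
numerical decisions behind `heveinscan`, and what the synthetic-data
generator does and does not emulate.

## Cysteine framework and loop numbering

A framework is the ordered set of cysteine positions; the pattern
string groups cysteines at distance 1 without a dash, so the 8C class
renders `C-C-CC-C-C-C-C`. Loop numbering follows the field's
convention for hevein-like peptides: backbone segments between
consecutive framework cysteines are numbered 1 upward, and **the empty
segment inside an adjacent CC pair carries no number**. For the 8C
framework this puts the S/φ/φ anchors in loop 3 (CysIV→CysV) and the
fourth aromatic in loop 4, which is the only numbering consistent with
where the chitin-binding residues are described to sit. The tail after
the last cysteine is counted as the final loop (loop 7 for 8C) for 8-
and 10-cysteine frameworks only; for other frameworks it is reported
separately as `c_term`, since the loop-7 convention is attested only
for the subfamilies that possess the C-terminal disulfide.

## Chitin-binding motif

The motif is `S-X-φ-X-φ-C-G-X-X-X-X-Y`, 12 residues, with anchors at
offsets 0 (Ser), 2 and 4 (aromatics), 5–6 (the Cys-Gly of the
framework) and 11 (the loop-4 aromatic). Two deliberate deviations
from the narrowest textbook definition:

- **φ defaults to {F, W, Y}**, not {Y, W}: ginkgotide-type peptides
  carry Phe at the first aromatic position (gB5 F21), so the literal
  two-letter set would reject the very peptides that define the class.
- **X positions are wildcards by default.** Known class members carry
  Lys (gB5 K20) and Gln (hevein) at X positions, contradicting a
  strict "small residue" reading; `x_mode="strict-small"` (set
  {G,A,S,T,C,N,D,P}) is available as an opt-in.

The final aromatic accepts {F, W, Y} as well, symmetric with φ; in
every class member observed it is Tyr, so this only widens the scanner
for divergent homologs.

## Pro-rich 8C classification

`pro_rich_8C` requires all of: exactly 8 cysteines; ≥1 motif hit;
proline count in [3, 6]; a Pro within the first 3 residues (N-flank)
and within the last 2 (C-flank). The flank windows are configuration,
not biology: "flanking" is not defined by a fixed window anywhere
authoritative, and 3/2 is the tightest choice that accepts the
canonical P2/P41 arrangement. Sequences containing `X` are returned
`unclassified` with a reason — an undetermined residue could hide a
cysteine or proline, so any call would be a guess.

## Mass arithmetic

Residue masses come from the pyteomics composition tables; the state
arithmetic is:

    M(k disulfides) = Σ residue masses + m(H₂O) − 2k·m(H)
    M(alkylated)    = Σ residue masses + m(H₂O) + n_Cys·m(reagent)

[M+H]⁺ adds the proton mass (1.007276 Da), not the hydrogen atom mass.
The default alkylation reagent is **carboxymethyl (58.00548 Da)** with
the *reduced* reference state, because the 8 × 58 ≈ 464 Da arithmetic
used to count cysteines from MALDI shifts corresponds to
reduced→alkylated with a ~58 Da adduct. Experimental write-ups of this
chemistry are not always internally consistent about the reagent
(iodoacetamide gives carbamidomethyl, 57.02146 Da); both reagents plus
a nominal 58.0 model are provided and the choice is a config field.
Shifts measured against the native (disulfide-bonded) species add one
hydrogen per half-cystine (`reference_state="native"`).
`cys_count_from_shift` rounds to the nearest integer count and rejects
shifts whose residual exceeds 25% of the per-Cys shift (configurable).

Net charge is a Henderson–Hasselbalch sum over the termini and the
D/E/C/Y/H/K/R side chains using the EMBOSS pKa set (N-term 8.6, C-term
3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); pI is found
by bisection on [0, 14] to |charge| < 1e−4 by default (the tolerance is
an argument; tighter tolerances sharpen the pH estimate). The charge
curve is strictly decreasing in pH, so bisection cannot fail; an
iteration cap guards it anyway.

## Precursor partitioning and the homolog filter

Rule-based partitioning places the signal/mature boundary at the first
Gly|Asp dipeptide whose Gly lies at positions 15–35 (signal peptides
of this family are ~20–30 aa), and the mature/C-tail boundary one
residue after the last framework cysteine (`mature_flank=1`, matching
the single flanking Pro after CysVIII in the Pro-rich class). Explicit
annotations always override the rule. Records without a detectable
site are returned unpartitioned with a diagnostic rather than guessed.

The five filter criteria are applied in a fixed order — odd Cys count
(evaluated on the mature domain when set), signal < 10 aa,
undetermined residues (`X` anywhere, or an unpartitionable record
under strict mode), identical full sequence from the same plant,
missing terminal Pro flanks — and each removed record is attributed to
the **first** criterion it violates. The reported per-criterion counts
therefore depend on the order, which is exposed as configuration; the
survivor set does not (except through the duplicate criterion, whose
keep-first rule is input-order dependent by design — only records that
are themselves kept shadow later same-plant copies, so every duplicate
removal points at an actual survivor). "Identical sequence from the
same plant" means identical full precursor *and* identical organism
string: identical mature domains from *different* plants are valid
distinct precursor records and are only merged later, by
`unique_mature_domains`.

C-tails shorter than 50 aa are called `cargo_free`, at or above 50
`cargo`. The threshold sits midway between the ~20-aa cargo-free tails
of the Pro-rich class and the smallest known protein cargo (a 126-aa
Barwin-like domain) and is a config field; the boundary is half-open
(50 itself is cargo).

## Disulfide enumeration

Connectivities are perfect matchings over abstract roman-numeral
cysteine labels, so the combinatorics is independent of any particular
sequence; `CysFramework` maps labels to positions. Enumeration is a
deterministic recursion (always pair the smallest unmatched label
first), output canonicalised and lexicographically ordered; with f
fixed pairs and 2k free cysteines the count is (2k−1)!!. Energies are
*inputs* (kcal/mol per pattern): computing structural energies is a
structure-calculation problem outside this package's scope, and only
the enumeration and argmin/ranking logic live here. Ranking is a
stable ascending sort, so equal energies preserve canonical order.

## Neighbor joining and profiles

p-distance (mismatches / compared sites) with pairwise gap deletion is
the default metric — the upstream analyses this mirrors do not name
their distance model — with a Poisson correction (−ln(1−p)) behind a
flag. Pairwise-deletion p-distances need not satisfy the triangle
inequality; nothing downstream assumes it.

NJ uses the standard Q-criterion with Studier–Keppler distance
updates. Ties in Q are broken by the lexicographically smallest label
pair, making topologies reproducible; negative branch lengths (possible
on non-additive input) are clamped to zero and logged. The unrooted
result is stored with a trifurcating root; n = 2 degenerates to a
single edge split into two d/2 half-lengths. On additive matrices the
implementation reproduces all leaf-to-leaf path lengths to ≤1e−9
(property-tested over random trees of 4–12 leaves, and cross-checked
against scikit-bio's independent NJ).

Profile matrices report per-column frequencies over the 20 residues
with gaps excluded from the denominator, and information content
R = log₂20 − H in bits. The small-sample (Miller–Madow) correction is
off by default since the logo tools this mirrors do not document
applying it; a flag enables it. All-gap columns are flagged, not
silently zeroed.

Translation and ORF finding use codon table 1 by default (table id is
an argument). ORFs run ATG→stop across all six frames; with nested
internal ATGs only the longest ORF per stop is reported by default —
the upstream ORF definition is ambiguous on nesting, and longest-per-
stop is this package's choice, with `longest_per_stop=False` exposing
all. Coordinates are 1-based inclusive on the forward strand
everywhere.

## Synthetic-data generator

The generator emits mature peptides *by construction* of the class
definition: the framework cysteines, the motif anchors (loop 3 =
`S·x·φ·x·φ`, loop 4 = `G·x₄·Y`), the flanking prolines and the
interior proline budget are placed deterministically from the seeded
RNG, and all remaining positions are drawn from a background pool that
**excludes Cys and Pro**. That exclusion is what makes ground truth
exact (no accidental framework or proline) and makes the screen decoys
pure — each violates exactly its assigned criterion, which is asserted
at generation time. Signal peptides additionally exclude Gly and Asp
so the cleavage dipeptide is unique, and C-tails exclude Cys so the
mature domain's last framework cysteine is unambiguous.

Defaults mirror the study conditions for the class: mature length
40–50 aa, 3–6 prolines, signal 20–30 aa (decoys 5–9), C-tail 20 aa
(cargo-free) with 126/254-aa modes emulating Barwin-like and class I
chitinase cargo, cleavage at G|D. The 85-record screen fixture
comprises 52 passing precursors whose mature domains collapse to 42
unique peptides — six shared across plants with multiplicities
(6,2,2,2,2,2), a construction chosen to satisfy the published totals
(52 precursors, 42 peptides, 6 shared, one of them in six plants),
which do not determine the multiplicities uniquely — plus decoys at
counts (1, 3, 3, 9, 17). Organisms are drawn from a 47-species
gymnosperm label pool.

What the generator does **not** emulate: realistic amino-acid
composition (background residues are uniform), sequence divergence and
phylogenetic signal among homologs, cysteines in C-tails (real protein
cargos contain them, so rule-based mature-end detection on real cargo
precursors needs annotations), translation-level noise, or partial
transcripts. Tests passing on synthetic data therefore demonstrate the
*logic* of the pipeline — framework detection, motif scanning, filter
attribution, boundary recovery — not robustness to real-world
composition biases.

## Problem sizes used in the test and acceptance runs

Property tests use 100 random trees (4–12 leaves) for NJ consistency,
10³ random peptides for the elemental-composition mass oracle, a few
hundred random sequences for the motif-scanner oracle, 10³ generated
peptides for generator/classifier agreement, and 300–500 precursors
for boundary recovery. These sizes give the properties exercised many
independent chances to fail while keeping the default suite fast to
run routinely.

## Known limitations

- Signal peptides are located by the G|D rule or annotations, not by a
  learned predictor; divergent cleavage sites need annotations.
- The rule-based mature-domain end (last framework Cys + 1) presumes a
  Cys-free C-tail; chimeric cargo precursors require annotations.
- The aligner is a plumbing-grade pairwise Needleman–Wunsch; multiple
  alignments must be produced upstream.
- Disulfide patterns are only enumerated and ranked; no energies or
  structures are computed.
- pI values depend on the pKa set; only the EMBOSS set ships, and
  published predictors using other sets will differ by a few tenths of
  a pH unit.
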