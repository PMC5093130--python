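# heveinscan

Sequence-level discovery and classification toolkit for **hevein-like
peptides** — small (~29–50 aa) cysteine- and glycine-rich plant defence
peptides that bind chitin, grouped into subfamilies by cysteine count
(6C, 8C, 10C). The package implements the in-silico side of
characterising a new **Pro-rich 8C class** of these peptides
(exemplified by the ginkgotides of *Ginkgo biloba*): given mature
peptide and precursor sequences, it answers which candidates belong to
the class, what their masses and disulfide connectivities can be, and
how the homologs relate phylogenetically.

It is aimed at peptide biochemists and plant genomics researchers
triaging transcriptome or EST screens for cysteine-rich peptides.

## What it computes

- **Cysteine framework and loops** — locates cysteines, renders the
  spacing pattern (the 8C class shows `C-C-CC-C-C-C-C` with a
  diagnostic adjacent-CC pair), and segments the backbone into
  intercysteine loops 1–7 (the empty CC gap carries no loop number).
- **Chitin-binding motif** — sliding-window scan for the 12-residue
  domain `S-X-φ-X-φ-C-G-X₄-Y` (φ aromatic) spanning loops 3–4; on gB5
  the anchors are S19, F21, Y23 and Y30.
- **Pro-rich 8C classification** — 8 cysteines ∧ motif present ∧ 3–6
  prolines ∧ Pro flanking both termini.
- **Mass arithmetic** — monoisotopic/average mass with
  `M = Σ residues + H₂O − 2k·m_H` for k disulfide bonds, S-alkylation
  adducts (58 Da/Cys), cysteine counting from reduction/alkylation mass
  shifts, [M+H]⁺, Henderson–Hasselbalch net charge and pI.
- **Disulfide combinatorics** — all perfect matchings of 2k cysteines
  into bonds (count (2k−1)!!), optionally with experimentally fixed
  pairs, and ranking by externally supplied structural energies.
- **Precursor parsing and the homolog filter** — signal | mature |
  C-tail partitioning at the conserved Gly|Asp cleavage site, cargo vs
  cargo-free C-tail calls, and the ordered five-criterion screen filter
  (odd Cys, signal <10 aa, undetermined residues, same-plant
  duplicates, missing Pro flanks) with cross-plant mature-domain
  deduplication.
- **Phylogenetics and logos** — p-distances from alignments,
  deterministic neighbor joining with Newick output, and per-column
  frequency / information-content matrices.
- **Synthetic data** — generators for class-conforming peptides and
  precursors with ground truth, including a deterministic 85-record
  screen fixture with labelled decoys.

## Worked example

```sh
$ printf ">gB5\nDPTCSVLGDFKCNPGRCCSKFNYCGSTAAYCGPGNCIAQCP\n" > gb5.fasta
$ heveinscan classify gb5.fasta
id    length  n_cys  pattern         subfamily  pro_rich_8C  motif_anchors  pro_positions
gB5   41      8      C-C-CC-C-C-C-C  8C         1            S19,21,23,30   2,14,33,41
```

gB5 is a 41-residue 8C peptide: the chitin-binding motif is anchored at
Ser19 with aromatics at 21, 23 and 30, and its four prolines sit at
positions 2, 14, 33 and 41 — flanking both termini — so it classifies
as Pro-rich 8C (`pro_rich_8C = 1`).

```sh
$ heveinscan mass gb5.fasta --disulfides auto
id    mass       mh_plus    kind           state
gB5   4241.6749  4242.6822  monoisotopic   4 disulfides
```

With all eight cysteines paired into four disulfide bonds the
monoisotopic mass is 4241.7 Da ([M+H]⁺ 4242.7 Da), matching an intact
MALDI-TOF measurement of the native peptide. The same library call is
`peptide_mass(seq, n_disulfides=4)`.

```sh
$ heveinscan enum-ss --n-cys 8 --fix II:V | tail -n +2 | wc -l
15
```

Fixing the CysII–CysV bond (e.g. from an unambiguous NOE) leaves 15
candidate connectivities for the remaining six cysteines; feeding
per-pattern structural energies via `--energies` ranks them and
recovers the native cystine-knot pattern
(I–IV, II–V, III–VI, VII–VIII) as the argmin.

```sh
$ heveinscan simulate --preset paper --seed 1 -o screen.fasta
$ heveinscan filter screen.fasta
criterion             removed  ids
odd_cys               1        hl053
short_signal          3        hl054,hl055,hl056
undetermined          3        hl057,hl058,hl059
duplicate_same_plant  9        ...
missing_pro_flanks    17       ...
survivors             52       ...
```

The synthetic 85-record screen is reduced to 52 precursor survivors,
whose mature domains collapse to 42 unique peptides (6 of them shared
across multiple plants).

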