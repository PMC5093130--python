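"""Cysteine-framework analysis and Pro-rich 8C classification.

Hevein-like peptides are small chitin-binding plant-defence peptides
grouped into subfamilies by cysteine count (6C, 8C, 10C).  The 8C
subfamily carries the framework C-C-CC-C-C-C-C with a diagnostic
adjacent-CC pair at cysteines III/IV; backbone segments between
consecutive framework cysteines are the intercysteine loops, numbered
1-7 with the empty gap inside the CC pair carrying no number.  The
chitin-binding domain is the 12-residue motif S-X-phi-X-phi-C-G-X4-Y
spanning loops 3 and 4 (one Ser plus three aromatics).

The Pro-rich 8C class is defined by four features on top of the 8C
framework: a chitin-binding motif, 3-6 prolines, and prolines flanking
both the N- and the C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
         "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]

#: aromatic residues accepted at the phi anchor positions.  The motif is
#: usually written with phi = Y or W, but ginkgotide-type peptides carry
#: Phe at the first aromatic position, so F is accepted by default.
DEFAULT_PHI_SET = frozenset("FWY")
#: residues counted as "small" when strict X matching is requested
STRICT_SMALL_SET = frozenset("GASTCNDP")

MOTIF_LEN = 12  # S X phi X phi C G X X X X Y


@dataclass(frozen=True)
class CysFramework:
    """Cysteine positions, spacing pattern and roman-numeral labels."""

    cys_positions: tuple[int, ...]
    pattern: str
    cys_labels: dict[str, int] = field(compare=False, default_factory=dict)

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


@dataclass(frozen=True)
class LoopDecomposition:
    """Intercysteine loop segmentation of a framework peptide.

    ``loops`` maps loop number to the backbone substring between
    consecutive cysteines; the tail after the last cysteine is the final
    loop for 8C/10C frameworks and is otherwise held in ``c_term``.
    """

    n_term: str
    loops: dict[int, str]
    c_term: str = ""


@dataclass(frozen=True)
class MotifDefinition:
    """The chitin-binding domain motif S-X-phi-X-phi-C-G-X4-Y."""

    phi_set: frozenset[str] = DEFAULT_PHI_SET
    y_set: frozenset[str] = DEFAULT_PHI_SET
    x_mode: str = "wildcard"  # or "strict-small"
    strict_small_set: frozenset[str] = STRICT_SMALL_SET

    def x_ok(self, res: str) -> bool:
        if self.x_mode == "wildcard":
            return True
        return res in self.strict_small_set


@dataclass(frozen=True)
class MotifHit:
    """One chitin-binding-motif match with its four anchor positions (1-based)."""

    ser_pos: int
    phi1_pos: int
    phi2_pos: int
    tyr_pos: int
    matched_window: str


@dataclass(frozen=True)
class ProMetrics:
    count: int
    positions: tuple[int, ...]
    n_flank: bool
    c_flank: bool


@dataclass(frozen=True)
class SubfamilyCall:
    subfamily: str  # 6C | 8C | 10C | unclassified
    pro_rich_8C: bool
    evidence: dict[str, bool] = field(compare=False, default_factory=dict)
    reason: str = ""


def detect_framework(seq: str) -> CysFramework:
    """Locate all cysteines and build the spacing pattern.

    Adjacent cysteines (distance 1) are grouped without a dash, so the
    gB5-type framework renders as ``C-C-CC-C-C-C-C``.  Zero cysteines
    yield an empty framework, not an error.
    """
    positions = tuple(i + 1 for i, res in enumerate(seq) if res == "C")
    groups: list[str] = []
    for i, pos in enumerate(positions):
        if i > 0 and pos == positions[i - 1] + 1:
            groups[-1] += "C"
        else:
            groups.append("C")
    labels = {ROMAN[i]: pos for i, pos in enumerate(positions)}
    return CysFramework(positions, "-".join(groups), labels)


def decompose_loops(seq: str, framework: CysFramework | None = None) -> LoopDecomposition:
    """Segment a peptide into intercysteine loops.

    The empty segment inside an adjacent-CC pair carries no loop number,
    so for the 8C framework loop 3 runs CysIV->CysV and loop 7 is the
    tail after CysVIII.  The tail is numbered as a loop only for 8- and
    10-cysteine frameworks; otherwise it is reported as ``c_term``.
    """
    fw = framework or detect_framework(seq)
    for lab, pos in fw.cys_labels.items():
        if seq[pos - 1] != "C":
            raise ValueError(f"framework inconsistent with sequence at Cys{lab} (pos {pos})")
    if not fw.cys_positions:
        return LoopDecomposition(n_term=seq, loops={}, c_term="")
    n_term = seq[: fw.cys_positions[0] - 1]
    loops: dict[int, str] = {}
    num = 0
    for a, b in zip(fw.cys_positions, fw.cys_positions[1:]):
        segment = seq[a : b - 1]
        if b == a + 1:
            continue  # inside an adjacent CC pair: unnumbered empty gap
        num += 1
        loops[num] = segment
    tail = seq[fw.cys_positions[-1] :]
    if fw.n_cys in (8, 10):
        loops[num + 1] = tail
        c_term = ""
    else:
        c_term = tail
    return LoopDecomposition(n_term=n_term, loops=loops, c_term=c_term)


def reconstruct(seq_framework: CysFramework, decomp: LoopDecomposition) -> str:
    """Rebuild the sequence from its loop decomposition (inverse check)."""
    parts = [decomp.n_term]
    positions = seq_framework.cys_positions
    pending = dict(decomp.loops)
    num = 0
    for a, b in zip(positions, positions[1:]):
        parts.append("C")
        if b == a + 1:
            continue
        num += 1
        parts.append(pending[num])
    if positions:
        parts.append("C")
    tail_loop = num + 1
    if tail_loop in pending:
        parts.append(pending[tail_loop])
    parts.append(decomp.c_term)
    return "".join(parts)


def pro_metrics(seq: str, n_window: int = 3, c_window: int = 2) -> ProMetrics:
    """Proline count, positions and terminal-flank booleans.

    ``n_flank`` is true iff a Pro occurs within the first ``n_window``
    residues, ``c_flank`` within the last ``c_window``.  The defaults
    (3 and 2) accept the P2/P41 arrangement typical of the class.
    """
    if not seq:
        raise ValueError("empty sequence")
    positions = tuple(i + 1 for i, res in enumerate(seq) if res == "P")
    n_flank = any(p <= n_window for p in positions)
    c_flank = any(p > len(seq) - c_window for p in positions)
    return ProMetrics(len(positions), positions, n_flank, c_flank)


def scan_chitin_motif(seq: str, motif: MotifDefinition | None = None) -> list[MotifHit]:
    """Slide the 12-residue chitin-binding motif over the sequence.

    Reports every window matching S at 1, aromatics at 3/5/12 and C-G at
    6-7 (anchor offsets 0,2,4,11 from the serine); X positions are
    wildcards by default or restricted to small residues in strict mode.
    """
    motif = motif or MotifDefinition()
    hits: list[MotifHit] = []
    for i in range(len(seq) - MOTIF_LEN + 1):
        w = seq[i : i + MOTIF_LEN]
        if (
            w[0] == "S"
            and w[2] in motif.phi_set
            and w[4] in motif.phi_set
            and w[5] == "C"
            and w[6] == "G"
            and w[11] in motif.y_set
            and all(motif.x_ok(w[j]) for j in (1, 3, 7, 8, 9, 10))
        ):
            hits.append(MotifHit(i + 1, i + 3, i + 5, i + 12, w))
    return hits


def classify_subfamily(
    seq: str,
    motif: MotifDefinition | None = None,
    *,
    pro_range: tuple[int, int] = (3, 6),
    n_window: int = 3,
    c_window: int = 2,
) -> SubfamilyCall:
    """Assign a hevein-like subfamily and test the Pro-rich 8C criteria.

    Subfamily is by cysteine count (6/8/10 -> 6C/8C/10C, anything else
    unclassified).  ``pro_rich_8C`` requires all five criteria: 8
    cysteines, a chitin-binding motif hit, 3-6 prolines, and Pro flanks
    at both termini.  Sequences containing 'X' cannot be classified
    (an undetermined residue could hide a Cys or Pro).
    """
    if "X" in seq:
        return SubfamilyCall("unclassified", False, {}, reason="undetermined residue 'X'")
    fw = detect_framework(seq)
    subfamily = {6: "6C", 8: "8C", 10: "10C"}.get(fw.n_cys, "unclassified")
    hits = scan_chitin_motif(seq, motif)
    pm = pro_metrics(seq, n_window, c_window)
    evidence = {
        "eight_cys": fw.n_cys == 8,
        "motif_present": bool(hits),
        "pro_count_in_range": pro_range[0] <= pm.count <= pro_range[1],
        "n_flank_pro": pm.n_flank,
        "c_flank_pro": pm.c_flank,
    }
    return SubfamilyCall(subfamily, all(evidence.values()), evidence)
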