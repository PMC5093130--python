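"""Synthetic hevein-like peptides and precursors with ground truth.

Generates mature peptides that satisfy a requested subfamily definition
by construction (cysteine framework, chitin-binding motif spanning
loops 3-4, proline count and terminal flanks for the Pro-rich class),
and three-domain precursors around them (signal peptide ending at a
Gly|Asp cleavage site, mature domain, C-terminal tail of 20 aa for the
cargo-free class or 126/254 aa emulating Barwin-like / class I
chitinase cargo).

``paper_fixture`` builds the deterministic 85-record screen used to
exercise the homolog filter end to end: 52 records passing all five
criteria (whose mature domains collapse to 42 unique peptides, six of
them shared across plants with multiplicities 6,2,2,2,2,2) plus five
decoy categories — 1 odd-cysteine, 3 short-signal, 3 with an
undetermined residue, 9 same-plant duplicates and 17 lacking terminal
Pro flanks — each decoy violating exactly its assigned criterion.

Design notes: random residues are drawn from a pool that excludes Cys
and Pro, so cysteine frameworks and proline placement are exactly as
constructed and decoys cannot accidentally violate a second criterion;
signal peptides additionally exclude Gly and Asp so the cleavage
dipeptide is unique; C-tails exclude Cys so the mature domain's last
framework cysteine is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hevein_core import (
    MotifDefinition,
    classify_subfamily,
    detect_framework,
    pro_metrics,
    scan_chitin_motif,
)
from .precursor_pipeline import FilterCriteria, PrecursorRecord, filter_homologs
from .seqio import PeptideRecord

#: background residue pool: the 20 standard residues minus Cys and Pro
BG_POOL = "ADEFGHIKLMNQRSTVWY"
#: signal-peptide pool: additionally no Gly/Asp, so the G|D site is unique
SIG_POOL = "AEFHIKLMNQRSTVWY"
#: C-tail pool: no Cys (keeps the mature framework's last Cys unambiguous)
TAIL_POOL = "ADEFGHIKLMNQRSTVWY"

AROMATICS = "FWY"

C_TAIL_LENGTHS = {"short": 20, "barwin": 126, "chitinase": 254}

#: gymnosperm species pool for organism labels (the screen's taxa are
#: dominated by Cupressaceae, Pinaceae, Podocarpaceae, Taxaceae,
#: Cephalotaxaceae and Stangeriaceae)
ORGANISMS = (
    "Ginkgo biloba", "Calocedrus decurrens", "Cunninghamia lanceolata",
    "Cupressus dupreziana", "Platycladus orientalis", "Sequoiadendron giganteum",
    "Taiwania cryptomerioides", "Pinus sylvestris", "Pinus taeda",
    "Picea abies", "Picea sitchensis", "Abies alba", "Larix decidua",
    "Pseudotsuga menziesii", "Cedrus atlantica", "Tsuga canadensis",
    "Juniperus communis", "Thuja plicata", "Chamaecyparis obtusa",
    "Cryptomeria japonica", "Sequoia sempervirens", "Metasequoia glyptostroboides",
    "Taxodium distichum", "Taxus baccata", "Torreya nucifera",
    "Cephalotaxus harringtonia", "Podocarpus macrophyllus", "Dacrydium cupressinum",
    "Nageia nagi", "Stangeria eriopus", "Cycas revoluta", "Zamia furfuracea",
    "Araucaria araucana", "Agathis australis", "Wollemia nobilis",
    "Welwitschia mirabilis", "Ephedra sinica", "Gnetum gnemon",
    "Abies grandis", "Pinus pinaster", "Pinus radiata", "Picea glauca",
    "Larix kaempferi", "Keteleeria davidiana", "Pseudolarix amabilis",
    "Sciadopitys verticillata", "Fokienia hodginsii",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the generator."""

    seed: int = 0
    subfamily: str = "pro_rich_8C"  # pro_rich_8C | 8C | 6C | 10C
    mature_len_range: tuple[int, int] = (40, 50)
    pro_count_range: tuple[int, int] = (3, 6)
    signal_len_range: tuple[int, int] = (20, 30)
    decoy_signal_len_range: tuple[int, int] = (5, 9)
    c_tail_mode: str = "short"
    cleavage_dipeptide: str = "GD"


@dataclass(frozen=True)
class GroundTruth:
    """Construction metadata for a generated record."""

    subfamily: str
    pro_rich: bool
    motif_ser_pos: int | None = None
    pro_positions: tuple[int, ...] = ()
    sig_end: int | None = None     # 1-based last residue of the signal
    mat_end: int | None = None     # 1-based last residue of the mature domain
    decoy_category: str | None = None


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` integers, each >= 1."""
    if total < parts:
        raise ValueError(f"cannot split {total} into {parts} nonempty parts")
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = [0, *cuts.tolist(), total]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _build_mature(
    rng: np.random.Generator,
    config: GeneratorConfig,
    *,
    subfamily: str | None = None,
    pro_flanks: bool = True,
    drop_last_cys: bool = False,
) -> tuple[str, GroundTruth]:
    """Assemble a mature peptide satisfying the requested definition.

    Layout (Pro-rich 8C): D P [x] | C loop1 C loop2 CC loop3 C loop4 C
    loop5 C loop6 C P, with loop3 = S x phi x phi (5 aa) and
    loop4 = G xxxx Y (6 aa) so the chitin-binding motif spans the
    CysIV-CysV region exactly as in the natural peptides.
    """
    subfamily = subfamily or config.subfamily
    pro_rich = subfamily == "pro_rich_8C"
    lo, hi = config.mature_len_range
    length = int(rng.integers(lo, hi + 1))
    nt_len = int(rng.integers(2, 4))  # N-terminal segment before CysI: 2-3 aa

    n_extra_cys = {"pro_rich_8C": 0, "8C": 0, "10C": 2, "6C": -2}[subfamily]
    # fixed budget: n_term + cysteines + loop3(5) + loop4(6) + tail(1)
    n_cys = 8 + n_extra_cys
    n_var_loops = {6: 2, 8: 4, 10: 6}[n_cys]  # loops drawn with free lengths
    fixed = nt_len + n_cys + 5 + 6 + 1
    var_total = length - fixed
    var = _split_lengths(rng, var_total, n_var_loops)

    use_flank_pro = pro_rich and pro_flanks
    if use_flank_pro:
        n_term = "DP" + _draw(rng, BG_POOL, nt_len - 2)
        tail = "P"
    else:
        n_term = "D" + _draw(rng, BG_POOL, nt_len - 1)
        tail = _draw(rng, BG_POOL, 1)

    loop3 = "S" + _draw(rng, BG_POOL, 1) + _draw(rng, AROMATICS, 1) \
        + _draw(rng, BG_POOL, 1) + _draw(rng, AROMATICS, 1)
    loop4 = "G" + _draw(rng, BG_POOL, 4) + "Y"
    var_loops = [_draw(rng, BG_POOL, n) for n in var]

    if pro_rich:
        # raise the Pro count into range by substituting background
        # residues in the free loops
        plo, phi = config.pro_count_range
        target = int(rng.integers(plo, phi + 1))
        extra = max(target - 2, 0)
        flat = [(i, j) for i, loop in enumerate(var_loops) for j in range(len(loop))]
        picks = rng.choice(len(flat), size=extra, replace=False)
        for k in picks:
            i, j = flat[k]
            var_loops[i] = var_loops[i][:j] + "P" + var_loops[i][j + 1 :]

    if n_cys == 6:
        l1, l2 = var_loops
        seq = n_term + "C" + l1 + "C" + l2 + "CC" + loop3 + "C" + loop4 + "C" + tail
    elif n_cys == 8:
        l1, l2, l5, l6 = var_loops
        seq = (n_term + "C" + l1 + "C" + l2 + "CC" + loop3 + "C" + loop4
               + "C" + l5 + "C" + l6 + "C" + tail)
    else:  # 10
        l1, l2, l5, l6, l7, l8 = var_loops
        seq = (n_term + "C" + l1 + "C" + l2 + "CC" + loop3 + "C" + loop4
               + "C" + l5 + "C" + l6 + "C" + l7 + "C" + l8 + "C" + tail)

    if drop_last_cys:
        last = seq.rfind("C")
        seq = seq[:last] + seq[last + 1 :]

    # motif serine = first residue of loop3: n_term, CysI, loop1, CysII,
    # loop2 and the CC pair precede it
    ser_pos = len(n_term) + len(var_loops[0]) + len(var_loops[1]) + 5
    truth = GroundTruth(
        subfamily=subfamily,
        pro_rich=pro_rich,
        motif_ser_pos=ser_pos,
        pro_positions=tuple(i + 1 for i, r in enumerate(seq) if r == "P"),
    )
    return seq, truth


def generate_peptide(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[PeptideRecord, GroundTruth]:
    """One mature peptide consistent with its labelled subfamily.

    The emitted sequence is re-checked against the classifier; a
    mismatch (impossible by construction, kept as a guard) raises.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    seq, truth = _build_mature(rng, config)
    call = classify_subfamily(seq)
    expected = "8C" if truth.subfamily == "pro_rich_8C" else truth.subfamily
    if call.subfamily != expected or call.pro_rich_8C != truth.pro_rich:
        raise RuntimeError(f"generator/classifier inconsistency for {seq}")
    rec = PeptideRecord(id=f"syn_{truth.subfamily}", sequence=seq,
                        description=f"synthetic {truth.subfamily} mature peptide")
    return rec, truth


def _build_precursor(
    rng: np.random.Generator,
    config: GeneratorConfig,
    rec_id: str,
    organism: str,
    *,
    mature: str | None = None,
    mature_truth: GroundTruth | None = None,
    signal_len: int | None = None,
    decoy_category: str | None = None,
    mature_kwargs: dict | None = None,
) -> tuple[PrecursorRecord, GroundTruth]:
    if mature is None:
        mature, mature_truth = _build_mature(rng, config, **(mature_kwargs or {}))
    if signal_len is None:
        lo, hi = config.signal_len_range
        signal_len = int(rng.integers(lo, hi + 1))
    signal = _draw(rng, SIG_POOL, signal_len - 1) + config.cleavage_dipeptide[0]
    c_tail = _draw(rng, TAIL_POOL, C_TAIL_LENGTHS[config.c_tail_mode])
    full = signal + mature + c_tail
    rec = PrecursorRecord(
        id=rec_id,
        full_sequence=full,
        organism=organism,
        signal=signal,
        mature=mature,
        c_tail=c_tail,
        cleavage_rule_used="generator annotation",
        description=f"synthetic precursor ({organism})",
    )
    truth = replace(
        mature_truth,
        sig_end=len(signal),
        mat_end=len(signal) + len(mature),
        decoy_category=decoy_category,
    )
    return rec, truth


def generate_precursor(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[PrecursorRecord, GroundTruth]:
    """One annotated three-domain precursor (signal | mature | C-tail)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _build_precursor(rng, config, "syn_precursor", "Ginkgo biloba")


# ---------------------------------------------------------------------------
# the 85-record screen fixture

#: per-criterion decoy counts of the screen composition
DECOY_COUNTS = {
    "odd_cys": 1,
    "short_signal": 3,
    "undetermined": 3,
    "duplicate_same_plant": 9,
    "missing_pro_flanks": 17,
}
#: multiplicities of the six mature domains shared across plants
SHARED_MULTIPLICITIES = (6, 2, 2, 2, 2, 2)
N_UNIQUE_MATURE = 42
N_SURVIVORS = 52


def _violated_criteria(rec: PrecursorRecord, criteria: FilterCriteria) -> set[str]:
    """Content criteria a record violates (duplicate handled by context)."""
    out = set()
    if detect_framework(rec.mature).n_cys % 2 == 1:
        out.add("odd_cys")
    if len(rec.signal) < criteria.min_signal_len:
        out.add("short_signal")
    if "X" in rec.full_sequence:
        out.add("undetermined")
    pm = pro_metrics(rec.mature, criteria.n_window, criteria.c_window)
    if not (pm.n_flank and pm.c_flank):
        out.add("missing_pro_flanks")
    return out


def paper_fixture(seed: int = 0) -> tuple[list[PrecursorRecord], list[GroundTruth]]:
    """Deterministic 85-record homolog-screen fixture.

    Returns records in a fixed deterministic order (same-plant
    duplicates always after their originals) together with per-record
    ground truth.  Filtering with default criteria leaves 52 survivors
    with removals (1, 3, 3, 9, 17); the survivors' mature domains
    collapse to 42 unique peptides, 6 of which span multiple plants.
    """
    rng = np.random.default_rng(seed)
    config = GeneratorConfig(seed=seed)
    criteria = FilterCriteria()

    # 42 distinct mature domains
    matures: list[tuple[str, GroundTruth]] = []
    seen: set[str] = set()
    while len(matures) < N_UNIQUE_MATURE:
        seq, truth = _build_mature(rng, config)
        if seq not in seen:
            seen.add(seq)
            matures.append((seq, truth))

    records: list[PrecursorRecord] = []
    truths: list[GroundTruth] = []
    counter = 0

    def add(rec: PrecursorRecord, truth: GroundTruth) -> None:
        records.append(rec)
        truths.append(truth)

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"hl{counter:03d}"

    # survivors: six shared domains at multiplicities (6,2,2,2,2,2), rest unique
    org_cursor = 0
    for g, mult in enumerate(SHARED_MULTIPLICITIES):
        seq, truth = matures[g]
        for _ in range(mult):
            organism = ORGANISMS[org_cursor]
            org_cursor += 1
            add(*_build_precursor(rng, config, next_id(), organism,
                                  mature=seq, mature_truth=truth))
    for g in range(len(SHARED_MULTIPLICITIES), N_UNIQUE_MATURE):
        seq, truth = matures[g]
        organism = ORGANISMS[org_cursor % len(ORGANISMS)]
        org_cursor += 1
        add(*_build_precursor(rng, config, next_id(), organism,
                              mature=seq, mature_truth=truth))
    survivors = list(records)

    # decoys violating exactly one criterion each
    def random_org() -> str:
        return ORGANISMS[int(rng.integers(0, len(ORGANISMS)))]

    for _ in range(DECOY_COUNTS["odd_cys"]):
        rec, truth = _build_precursor(
            rng, config, next_id(), random_org(),
            decoy_category="odd_cys", mature_kwargs={"drop_last_cys": True},
        )
        add(rec, truth)
    lo, hi = config.decoy_signal_len_range
    for _ in range(DECOY_COUNTS["short_signal"]):
        rec, truth = _build_precursor(
            rng, config, next_id(), random_org(),
            signal_len=int(rng.integers(lo, hi + 1)), decoy_category="short_signal",
        )
        add(rec, truth)
    for _ in range(DECOY_COUNTS["undetermined"]):
        rec, truth = _build_precursor(rng, config, next_id(), random_org(),
                                      decoy_category="undetermined")
        # plant a single 'X' on a background (non-C, non-P) residue inside
        # the mature domain
        m = rec.mature
        bg_idx = [i for i, r in enumerate(m) if r in BG_POOL][1:-1]
        i = int(rng.choice(bg_idx))
        new_m = m[:i] + "X" + m[i + 1 :]
        rec = replace(rec, mature=new_m,
                      full_sequence=rec.signal + new_m + rec.c_tail)
        add(rec, truth)
    for _ in range(DECOY_COUNTS["missing_pro_flanks"]):
        rec, truth = _build_precursor(
            rng, config, next_id(), random_org(),
            decoy_category="missing_pro_flanks", mature_kwargs={"pro_flanks": False},
        )
        add(rec, truth)

    # same-plant duplicates of nine distinct survivors, appended after
    # their originals (keep-first semantics removes the copy)
    dup_sources = rng.choice(len(survivors), size=DECOY_COUNTS["duplicate_same_plant"],
                             replace=False)
    for i in sorted(int(k) for k in dup_sources):
        src = survivors[i]
        src_truth = truths[i]  # survivors occupy the first positions in order
        rec = replace(src, id=next_id())
        add(rec, replace(src_truth, decoy_category="duplicate_same_plant"))

    # generation-time purity check: every decoy violates exactly its
    # assigned content criterion; duplicates violate none by content
    for rec, truth in zip(records, truths):
        violated = _violated_criteria(rec, criteria)
        if truth.decoy_category in (None, "duplicate_same_plant"):
            assert not violated, (rec.id, violated)
        else:
            assert violated == {truth.decoy_category}, (rec.id, violated)
    assert len(records) == 85

    return records, truths
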