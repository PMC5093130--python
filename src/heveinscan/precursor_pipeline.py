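"""Precursor domain parsing and the five-criterion homolog filter.

Hevein-like peptide precursors share a three-domain architecture: an ER
signal peptide, the mature hevein-like domain, and a C-terminal tail.
In the Pro-rich 8C class the signal peptide is cleaved at a conserved
Gly|Asp bond and the tail is short (~20 aa) and cargo-free, whereas
other 8C/10C precursors carry a protein cargo in the tail (a
Barwin-like protein, 126 aa, or a class I chitinase, 254 aa).

Candidate homologs from a sequence-similarity screen are reduced by an
ordered five-criterion filter — odd cysteine count, short signal
peptide (<10 aa), undetermined residues, same-plant duplicates, missing
terminal Pro flanks — followed by cross-plant deduplication of mature
domains (identical mature peptides from different plants are distinct
precursor records but one peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .hevein_core import detect_framework, pro_metrics

logger = logging.getLogger(__name__)

#: criterion names in their canonical application order
CRITERIA_ORDER = (
    "odd_cys",
    "short_signal",
    "undetermined",
    "duplicate_same_plant",
    "missing_pro_flanks",
)


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor sequence, optionally partitioned into its three domains."""

    id: str
    full_sequence: str
    organism: str = ""
    signal: str | None = None
    mature: str | None = None
    c_tail: str | None = None
    cleavage_rule_used: str = ""
    description: str = ""

    @property
    def sequence(self) -> str:  # FASTA-writing compatibility
        return self.full_sequence

    @property
    def partitioned(self) -> bool:
        return self.signal is not None and self.mature is not None and self.c_tail is not None

    def __post_init__(self) -> None:
        if self.partitioned and (self.signal + self.mature + self.c_tail) != self.full_sequence:
            raise ValueError(
                f"record {self.id!r}: domains do not concatenate to the full sequence"
            )


@dataclass(frozen=True)
class FilterCriteria:
    """Parameters of the five-criterion homolog filter."""

    order: tuple[str, ...] = CRITERIA_ORDER
    min_signal_len: int = 10
    n_window: int = 3
    c_window: int = 2
    strict: bool = True  # unevaluable criterion counts as a violation

    def __post_init__(self) -> None:
        unknown = set(self.order) - set(CRITERIA_ORDER)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")


@dataclass
class FilterReport:
    input_count: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)

    @property
    def removed_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}


@dataclass(frozen=True)
class CargoCall:
    status: str  # cargo_free | cargo
    c_tail_length: int
    threshold: int = 50


# ---------------------------------------------------------------------------
# domain partitioning

#: window (1-based positions of the signal's last residue) in which the
#: Gly|Asp cleavage site is searched
DEFAULT_CLEAVAGE_WINDOW = (15, 35)


def partition_domains(
    full_sequence: str,
    record_id: str = "",
    organism: str = "",
    annotation: tuple[int, int] | None = None,
    cleavage_dipeptide: str = "GD",
    cleavage_window: tuple[int, int] = DEFAULT_CLEAVAGE_WINDOW,
    mature_flank: int = 1,
) -> PrecursorRecord:
    """Partition a precursor into signal / mature / C-tail.

    With ``annotation`` (1-based positions of the last signal residue
    and the last mature residue) the boundaries are used verbatim.
    Otherwise the signal ends at the first Gly|Asp dipeptide whose Gly
    lies inside ``cleavage_window``, and the mature domain runs through
    the last cysteine of the detected framework plus ``mature_flank``
    residues (Pro-rich peptides carry a single flanking Pro after the
    final cysteine).  If no cleavage site is found the record is
    returned unpartitioned with a diagnostic in ``cleavage_rule_used``.
    """
    if annotation is not None:
        sig_end, mat_end = annotation
        if not 0 < sig_end < mat_end <= len(full_sequence):
            raise ValueError(f"record {record_id!r}: invalid annotation {annotation}")
        return PrecursorRecord(
            id=record_id,
            full_sequence=full_sequence,
            organism=organism,
            signal=full_sequence[:sig_end],
            mature=full_sequence[sig_end:mat_end],
            c_tail=full_sequence[mat_end:],
            cleavage_rule_used="annotation",
        )
    if len(full_sequence) < 30:
        raise ValueError(
            f"record {record_id!r}: rule-based partitioning needs >= 30 aa, got {len(full_sequence)}"
        )
    lo, hi = cleavage_window
    sig_end = None
    for pos in range(lo, min(hi, len(full_sequence) - 1) + 1):  # pos = Gly position, 1-based
        if full_sequence[pos - 1 : pos + 1] == cleavage_dipeptide:
            sig_end = pos
            break
    if sig_end is None:
        logger.warning(
            "record %r: no %s cleavage site in window %s; left unpartitioned",
            record_id, cleavage_dipeptide, cleavage_window,
        )
        return PrecursorRecord(
            id=record_id,
            full_sequence=full_sequence,
            organism=organism,
            cleavage_rule_used=f"no {cleavage_dipeptide} site in window {cleavage_window}",
        )
    rest = full_sequence[sig_end:]
    fw = detect_framework(rest)
    if not fw.cys_positions:
        return PrecursorRecord(
            id=record_id,
            full_sequence=full_sequence,
            organism=organism,
            cleavage_rule_used="no cysteine framework after signal",
        )
    mat_end = sig_end + min(fw.cys_positions[-1] + mature_flank, len(rest))
    return PrecursorRecord(
        id=record_id,
        full_sequence=full_sequence,
        organism=organism,
        signal=full_sequence[:sig_end],
        mature=full_sequence[sig_end:mat_end],
        c_tail=full_sequence[mat_end:],
        cleavage_rule_used=f"{cleavage_dipeptide[0]}|{cleavage_dipeptide[1]} rule",
    )


def cargo_classification(precursor: PrecursorRecord, threshold: int = 50) -> CargoCall:
    """Classify the C-terminal tail as cargo-free (< threshold aa) or cargo."""
    if precursor.c_tail is None:
        raise ValueError(f"record {precursor.id!r}: c_tail not set")
    n = len(precursor.c_tail)
    return CargoCall("cargo_free" if n < threshold else "cargo", n, threshold)


# ---------------------------------------------------------------------------
# homolog filter


def _violates(
    rec: PrecursorRecord,
    criterion: str,
    criteria: FilterCriteria,
    seen_same_plant: set[tuple[str, str]],
) -> bool:
    if criterion == "odd_cys":
        target = rec.mature if rec.mature is not None else rec.full_sequence
        return detect_framework(target).n_cys % 2 == 1
    if criterion == "short_signal":
        if rec.signal is None:
            return criteria.strict
        return len(rec.signal) < criteria.min_signal_len
    if criterion == "undetermined":
        return "X" in rec.full_sequence or (criteria.strict and not rec.partitioned)
    if criterion == "duplicate_same_plant":
        return (rec.organism, rec.full_sequence) in seen_same_plant
    if criterion == "missing_pro_flanks":
        if rec.mature is None:
            return criteria.strict
        pm = pro_metrics(rec.mature, criteria.n_window, criteria.c_window)
        return not (pm.n_flank and pm.c_flank)
    raise ValueError(f"unknown criterion {criterion!r}")


def filter_homologs(
    records: list[PrecursorRecord], criteria: FilterCriteria | None = None
) -> tuple[list[PrecursorRecord], FilterReport]:
    """Apply the ordered five-criterion filter.

    Each removed record is attributed to the FIRST criterion it
    violates.  The same-plant duplicate criterion keeps the first
    occurrence (input order) of an identical full sequence from the
    same organism and removes later copies.
    """
    criteria = criteria or FilterCriteria()
    report = FilterReport(input_count=len(records))
    report.removed = {c: [] for c in criteria.order}
    survivors: list[PrecursorRecord] = []
    seen_same_plant: set[tuple[str, str]] = set()
    for rec in records:
        hit = None
        for criterion in criteria.order:
            if _violates(rec, criterion, criteria, seen_same_plant):
                hit = criterion
                break
        # a record only shadows later same-plant copies if it was kept
        if hit is None:
            survivors.append(rec)
            report.survivors.append(rec.id)
            seen_same_plant.add((rec.organism, rec.full_sequence))
        else:
            report.removed[hit].append(rec.id)
    return survivors, report


def unique_mature_domains(
    survivors: list[PrecursorRecord],
) -> dict[str, list[tuple[PrecursorRecord, str]]]:
    """Group survivors by exact mature-domain sequence.

    Identical mature peptides expressed in multiple plants (with
    different signals and/or tails) form one group with several
    members.  Records without a mature domain raise.
    """
    missing = [r.id for r in survivors if r.mature is None]
    if missing:
        raise ValueError(f"mature domain unset for record(s) {missing}")
    groups: dict[str, list[tuple[PrecursorRecord, str]]] = {}
    for rec in survivors:
        groups.setdefault(rec.mature, []).append((rec, rec.organism))
    return groups


def multi_plant_groups(
    groups: dict[str, list[tuple[PrecursorRecord, str]]],
) -> dict[str, list[str]]:
    """Subset of groups whose members span more than one organism."""
    out = {}
    for mature, members in groups.items():
        organisms = sorted({org for _, org in members})
        if len(organisms) > 1:
            out[mature] = organisms
    return out
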