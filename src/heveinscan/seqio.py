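"""Sequence I/O and transcript-to-protein derivation.

Reads and writes FASTA, translates nucleotide transcripts in all six
frames, and finds open reading frames (ORFs).  An ORF is the region
between a start codon (ATG) and the first in-frame stop codon (TAA, TAG
or TGA); coordinates are reported 1-based inclusive on the forward
strand, matching the residue-numbering convention used throughout this
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NT_ALPHABET = set("ACGTN")
#: the 20 standard residues plus 'X' for undetermined positions
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

FRAMES = (1, 2, 3, -1, -2, -3)

#: default minimum ORF length in codons; small CRP precursors (~60-110 aa)
#: must pass while suppressing spurious short ORFs
DEFAULT_MIN_AA = 25


class SequenceError(ValueError):
    """Raised for malformed or out-of-alphabet sequence input."""


@dataclass(frozen=True)
class NucleotideRecord:
    """A nucleotide sequence (e.g. an EST transcript)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"empty nucleotide sequence for record {self.id!r}")
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid nucleotide symbol(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideRecord:
    """An amino-acid sequence (mature peptide or precursor)."""

    id: str
    sequence: str
    organism: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"empty peptide sequence for record {self.id!r}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residue symbol(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfHit:
    """One open reading frame.

    ``nt_start``/``nt_end`` are 1-based inclusive coordinates on the
    forward strand, covering start codon through the last codon of the
    protein (the stop codon is not included in the span).  ``partial``
    marks ORFs that ran off the end of the sequence without a stop.
    """

    frame: int
    nt_start: int
    nt_end: int
    protein: str
    partial: bool = False


# ---------------------------------------------------------------------------
# translation


def six_frame_translate(nt: NucleotideRecord, table: int = 1) -> dict[int, str]:
    """Translate a transcript in all six reading frames.

    Frames +1..+3 translate the forward strand at offsets 0..2; frames
    -1..-3 translate the reverse complement at the same offsets.
    Trailing partial codons are dropped, stops render as ``*`` and
    codons containing ``N`` render as ``X``.
    """
    if len(nt) < 3:
        raise SequenceError(
            f"record {nt.id!r}: need at least one full codon, got {len(nt)} nt"
        )
    fwd = Seq(nt.sequence)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for frame in FRAMES:
        strand = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        sub = strand[offset : offset + 3 * ((len(strand) - offset) // 3)]
        out[frame] = str(sub.translate(table=table))
    return out


def _frame_of(sub_offset: int, reverse: bool) -> int:
    return -(sub_offset + 1) if reverse else sub_offset + 1


def _orf_coords(frame: int, aa_start: int, aa_end: int, seqlen: int) -> tuple[int, int]:
    """Forward-strand 1-based inclusive span for aa indices [aa_start, aa_end)."""
    offset = abs(frame) - 1
    first = offset + 3 * aa_start          # 0-based on translated strand
    last = offset + 3 * aa_end - 1
    if frame > 0:
        return first + 1, last + 1
    # reverse strand: position j on the reverse complement is seqlen-1-j forward
    return seqlen - last, seqlen - first


def find_orfs(
    nt: NucleotideRecord,
    min_aa: int = DEFAULT_MIN_AA,
    *,
    table: int = 1,
    include_partial: bool = False,
    longest_per_stop: bool = True,
) -> list[OrfHit]:
    """Find ATG-to-stop ORFs in all six frames.

    By default only the longest ORF per stop codon (i.e. from the first
    in-frame ATG) is reported; ``longest_per_stop=False`` also reports
    ORFs from nested internal ATGs.  ORFs reaching the end of the
    sequence without a stop are reported, flagged partial, only when
    ``include_partial`` is set.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    translations = six_frame_translate(nt, table=table)
    hits: list[OrfHit] = []
    for frame, aa in translations.items():
        starts: list[int] = []
        for i, res in enumerate(aa):
            if res == "M":
                starts.append(i)
            if res == "*":
                for j, s in enumerate(starts):
                    if longest_per_stop and j > 0:
                        break
                    protein = aa[s:i]
                    if len(protein) >= min_aa:
                        a, b = _orf_coords(frame, s, i, len(nt))
                        hits.append(OrfHit(frame, a, b, protein))
                starts = []
        if include_partial and starts:
            for j, s in enumerate(starts):
                if longest_per_stop and j > 0:
                    break
                protein = aa[s:]
                if len(protein) >= min_aa:
                    a, b = _orf_coords(frame, s, len(aa), len(nt))
                    hits.append(OrfHit(frame, a, b, protein, partial=True))
    hits.sort(key=lambda h: (h.nt_start, h.nt_end, h.frame))
    return hits


# ---------------------------------------------------------------------------
# FASTA


def _dedupe_ids(records: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    seen: dict[str, int] = {}
    out = []
    for rid, seq, desc in records:
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid = new_id
        else:
            seen[rid] = 0
        out.append((rid, seq, desc))
    return out


def read_fasta(path: str | Path, kind: str = "protein") -> list:
    """Read a FASTA file into peptide or nucleotide records.

    Sequences are uppercased on read.  Duplicate ids are suffixed with
    ``_1``, ``_2``, ... and logged; empty records raise.
    """
    raw = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceError(f"empty sequence for record {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        raw.append((rec.id, seq, desc))
    raw = _dedupe_ids(raw)
    cls = PeptideRecord if kind == "protein" else NucleotideRecord
    return [cls(id=r, sequence=s, description=d) for r, s, d in raw]


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    seqrecs = []
    for rec in records:
        desc = getattr(rec, "description", "") or ""
        seqrecs.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
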