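"""Sequence/alignment records, FASTA and Stockholm I/O, identity and redundancy filtering."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import GAP, VALID_RESIDUES

ROUND_PREFIXES = ("DP", "TEP", "ESM")


@dataclass
class SequenceRecord:
    """A protein sequence with optional screening metadata."""

    id: str
    residues: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES - {GAP}
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid residues {sorted(bad)}")

    @property
    def round_label(self) -> str | None:
        """Screening-round label parsed from the id prefix (DP/TEP/ESM)."""
        for p in ROUND_PREFIXES:
            if self.id.startswith(p):
                return p
        return self.metadata.get("round")

    def degapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), dict(self.metadata))

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length gapped rows."""

    def __init__(self, rows: Sequence[SequenceRecord]):
        rows = list(rows)
        if not rows:
            raise ValueError("alignment must contain at least one row")
        n = len(rows[0].residues)
        for r in rows:
            if len(r.residues) != n:
                raise ValueError(f"row {r.id!r} has length {len(r.residues)} != {n}")
        seen: set[str] = set()
        for r in rows:
            if r.id in seen:
                raise ValueError(f"duplicate id {r.id!r}")
            seen.add(r.id)
        self.rows = rows
        self.n_columns = n

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, rid: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)

    def gap_fractions(self) -> np.ndarray:
        arr = np.array([list(r.residues) for r in self.rows])
        return (arr == GAP).mean(axis=0)

    def degapped(self) -> list[SequenceRecord]:
        return [r.degapped() for r in self.rows]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([r for r in self.rows if r.id in wanted])


def _check_unique(records: list[SequenceRecord]) -> list[SequenceRecord]:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate id {r.id!r}")
        seen.add(r.id)
    return records


def parse_fasta(source) -> list[SequenceRecord]:
    """Read FASTA from a path or text stream into SequenceRecords (order kept)."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records = [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return _check_unique(records)


def write_fasta(records: Iterable[SequenceRecord], dest, width: int = 60) -> None:
    handle = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for r in records:
            handle.write(f">{r.id}\n")
            for i in range(0, len(r.residues), width):
                handle.write(r.residues[i : i + width] + "\n")
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


def parse_alignment_fasta(source) -> Alignment:
    return Alignment(parse_fasta(source))


def write_alignment_fasta(aln: Alignment, dest) -> None:
    write_fasta(aln.rows, dest)


def parse_stockholm(source) -> Alignment:
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        bio_aln = AlignIO.read(handle, "stockholm")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    rows = [SequenceRecord(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in bio_aln]
    return Alignment(_check_unique(rows))


def write_stockholm(aln: Alignment, dest) -> None:
    bio = AlignIO.MultipleSeqAlignment(
        [_BioRecord(Seq(r.residues), id=r.id, description="") for r in aln.rows]
    )
    handle = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        AlignIO.write(bio, handle, "stockholm")
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    denominator: str = "shorter",
) -> float:
    """Fraction of identical aligned positions after global affine alignment.

    The denominator is the shorter sequence's length by default ("alignment"
    uses the number of aligned columns instead). 'X' never counts as a match.
    """
    from .msa import needleman_wunsch  # local import to avoid a cycle

    _, row_a, row_b = needleman_wunsch(
        a.residues, b.residues, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend
    )
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != GAP and x != "X"
    )
    if denominator == "shorter":
        denom = min(len(a.residues), len(b.residues))
    elif denominator == "alignment":
        denom = len(row_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return matches / denom


def greedy_identity_filter(
    candidates: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord] = (),
    threshold: float = 0.90,
    **identity_kwargs,
) -> list[SequenceRecord]:
    """Greedy redundancy filter: scan candidates in order, drop any with
    identity >= threshold to any reference or any previously retained candidate."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    retained: list[SequenceRecord] = []
    for cand in candidates:
        keep = True
        for other in list(references) + retained:
            if pairwise_identity(cand, other, **identity_kwargs) >= threshold:
                keep = False
                break
        if keep:
            retained.append(cand)
    return retained


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
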