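"""Sequence and table I/O with shared record types.

Coordinate convention: every coordinate exposed by this package is 1-based
inclusive, matching the residue numbering used in protein databases
(e.g. a domain spanning "residues 409-477"). Internal code may convert to
0-based half-open slices, but those never cross a public API boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("atx2kit")

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_STRICT_ALPHABET = set("ACGT")

#: twenty canonical amino acids, without the X wildcard
AMINO_ACIDS = sorted(set("ACDEFGHIKLMNPQRSTVWY"))


class ValidationError(ValueError):
    """Raised when an input record violates a declared invariant."""


class AlphabetError(ValidationError):
    """Raised when an operation receives a record of the wrong alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence.

    ``alphabet`` is ``"protein"`` or ``"dna"``; residues are stored
    uppercase. In strict mode residues outside the declared alphabet are
    rejected; in lenient mode unknown protein residues are mapped to ``X``
    (with a logged warning).
    """

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "dna"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self, strict: bool = True) -> "SequenceRecord":
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_STRICT_ALPHABET
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in allowed]
        if not bad:
            return self
        if strict:
            pos, c = bad[0]
            raise ValidationError(
                f"record {self.id!r}: illegal {self.alphabet} residue {c!r} at position {pos}"
            )
        if self.alphabet == "protein":
            logger.warning("record %r: %d unknown residues mapped to X", self.id, len(bad))
            fixed = "".join(c if c in allowed else "X" for c in self.residues)
            return SequenceRecord(self.id, fixed, self.alphabet, self.description)
        return self


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain on a protein, 1-based inclusive coordinates."""

    protein_id: str
    label: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain {self.label!r} on {self.protein_id!r}: "
                f"invalid span {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BlastHit:
    """One row of a 12-column tabular (outfmt 6) hit file."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if self.query_start > self.query_end or self.subject_start > self.subject_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: start > end"
            )


# ---------------------------------------------------------------------------
# coordinate helpers

def to_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return lo + 1, hi


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "protein", strict: bool = True) -> List[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, residues are uppercased, CRLF line endings are
    tolerated (Biopython handles them). Empty files yield an empty list.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sr = SequenceRecord(
            id=rec.id,
            residues=str(rec.seq),
            alphabet=alphabet,
            description=rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description,
        )
        records.append(sr.validate(strict=strict))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# domain tables (TSV with header)

_DOMAIN_COLUMNS = ("protein_id", "label", "start", "end")


def read_domain_table(path: str | Path) -> List[DomainAnnotation]:
    """Read a TSV of domain annotations (protein_id, label, start, end[, source])."""
    annotations: List[DomainAnnotation] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\r\n").split("\t")
        for col in _DOMAIN_COLUMNS:
            if col not in header:
                raise ValidationError(f"{path}: missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\r\n").split("\t")
            try:
                ann = DomainAnnotation(
                    protein_id=fields[idx["protein_id"]],
                    label=fields[idx["label"]],
                    start=int(fields[idx["start"]]),
                    end=int(fields[idx["end"]]),
                    source=fields[idx["source"]] if "source" in idx and len(fields) > idx["source"] else "",
                )
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            annotations.append(ann)
    return annotations


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tstart\tend\tsource\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.label}\t{a.start}\t{a.end}\t{a.source}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def read_blast_tabular(path: str | Path) -> List[BlastHit]:
    """Read a 12-column tab-separated BLAST hit table (outfmt 6 field order)."""
    hits: List[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tabular(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t{h.align_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.query_start}\t{h.query_end}\t"
                f"{h.subject_start}\t{h.subject_end}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )
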