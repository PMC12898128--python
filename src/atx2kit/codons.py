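"""Run-length codon notation: parsing, expansion, translation, summaries.

Repeat-encoding DNA is conventionally written in a compact run-length
notation such as ``(CAG)_8_-CAA-(CAG)_4_-CAA-(CAG)_8_`` (the canonical
healthy 22Q allele of human ATXN2). This module parses that notation in
the dialects found in print (subscript markup ``(XYZ)_n_``, plain
``(XYZ)n``, bare codon runs, hyphens/line breaks, ``**`` bold markers),
expands it to DNA, translates it with the standard genetic code, and
summarizes the repeat structure of the encoded peptide at codon level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Tuple

from Bio.Seq import Seq

from .io import SequenceRecord, ValidationError

_DNA_BASES = set("ACGT")


class ParseError(ValueError):
    """Raised on malformed run-length notation; carries a character offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class CodonRunLength:
    """An ordered list of (codon, count) runs."""

    runs: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        for codon, count in self.runs:
            if len(codon) != 3 or not set(codon) <= _DNA_BASES:
                raise ValidationError(f"invalid codon {codon!r}")
            if count < 1:
                raise ValidationError(f"invalid run count {count} for codon {codon}")

    @property
    def n_codons(self) -> int:
        return sum(count for _, count in self.runs)

    def canonicalize(self) -> "CodonRunLength":
        """Merge adjacent runs of the same codon."""
        merged: List[Tuple[str, int]] = []
        for codon, count in self.runs:
            if merged and merged[-1][0] == codon:
                merged[-1] = (codon, merged[-1][1] + count)
            else:
                merged.append((codon, count))
        return CodonRunLength(tuple(merged))


_TOKEN = re.compile(
    r"\(([A-Za-z]+)\)(?:_(\d+)_|(\d+))?"  # (XYZ)_n_, (XYZ)n, (XYZ)
    r"|([A-Za-z]+)"  # bare letter run, split into triplets
)


def parse_runlength(text: str) -> CodonRunLength:
    """Parse run-length codon notation into textual-order runs.

    Hyphens, whitespace and ``**`` bold markers are ignored. A bare letter
    run is split into consecutive triplets (printed strings often abut
    codons, e.g. ``CAA**ATG**`` reads ``CAAATG`` once markup is stripped).
    Runs are not merged; call :meth:`CodonRunLength.canonicalize` for the
    canonical form.
    """
    runs: List[Tuple[str, int]] = []
    pos = 0
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch in "-* \t\n\r":
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {ch!r}", pos)
        if m.group(1) is not None:
            codon = m.group(1).upper()
            if len(codon) != 3:
                raise ParseError(f"codon token {codon!r} has length {len(codon)} != 3", pos)
            if not set(codon) <= _DNA_BASES:
                raise ParseError(f"illegal base in codon {codon!r}", pos)
            count_str = m.group(2) or m.group(3)
            count = int(count_str) if count_str else 1
            if count == 0:
                raise ParseError(f"zero repeat count for codon {codon!r}", pos)
            runs.append((codon, count))
        else:
            bare = m.group(4).upper()
            if len(bare) % 3 != 0:
                raise ParseError(
                    f"bare codon run {bare!r} has length {len(bare)}, not a multiple of 3", pos
                )
            if not set(bare) <= _DNA_BASES:
                raise ParseError(f"illegal base in {bare!r}", pos)
            for k in range(0, len(bare), 3):
                runs.append((bare[k : k + 3], 1))
        pos = m.end()
    return CodonRunLength(tuple(runs))


def expand(runs: CodonRunLength, seq_id: str = "expanded") -> SequenceRecord:
    """Expand run-length codons to a DNA record (length 3 x total codons)."""
    dna = "".join(codon * count for codon, count in runs.runs)
    return SequenceRecord(id=seq_id, residues=dna, alphabet="dna")


def translate(dna: SequenceRecord, strict: bool = True) -> SequenceRecord:
    """Translate DNA with the standard nuclear genetic code.

    In strict mode an internal stop codon raises; length must be a
    multiple of 3 in either mode.
    """
    if dna.alphabet != "dna":
        raise ValidationError(f"translate requires a dna record, got {dna.alphabet}")
    if len(dna.residues) % 3 != 0:
        raise ValidationError(
            f"record {dna.id!r}: length {len(dna.residues)} not a multiple of 3"
        )
    protein = str(Seq(dna.residues).translate())
    if strict and "*" in protein:
        raise ValidationError(
            f"record {dna.id!r}: stop codon at codon {protein.index('*') + 1}"
        )
    return SequenceRecord(id=dna.id, residues=protein.replace("*", "X"), alphabet="protein")


def decompose(dna: SequenceRecord) -> CodonRunLength:
    """Inverse of :func:`expand`: canonical run-length form of raw DNA."""
    if len(dna.residues) % 3 != 0:
        raise ValidationError(
            f"record {dna.id!r}: length {len(dna.residues)} not a multiple of 3"
        )
    codons = [dna.residues[i : i + 3] for i in range(0, len(dna.residues), 3)]
    runs: List[Tuple[str, int]] = []
    for codon in codons:
        if runs and runs[-1][0] == codon:
            runs[-1] = (codon, runs[-1][1] + 1)
        else:
            runs.append((codon, 1))
    return CodonRunLength(tuple(runs))


@dataclass(frozen=True)
class RepeatCodonSummary:
    """Codon-level summary of a repeat-encoding DNA stretch.

    total_target: codons translating to the target residue.
    interruption_events: maximal non-target residue runs in the translated
        peptide, as (codon_start, codon_end, residue_run) with 1-based
        inclusive codon indices.
    codon_usage: counts of each codon encoding the target residue.
    longest_pure_run: longest uninterrupted stretch of the target residue.
    """

    target: str
    total_target: int
    interruption_events: Tuple[Tuple[int, int, str], ...]
    codon_usage: Dict[str, int]
    longest_pure_run: int

    @property
    def n_codons(self) -> int:
        return self.total_target + sum(e - s + 1 for s, e, _ in self.interruption_events)


def summarize_repeat_dna(runs: CodonRunLength, target: str = "Q") -> RepeatCodonSummary:
    """Summarize a repeat-encoding codon string with respect to one residue."""
    dna = expand(runs)
    peptide = translate(dna).residues
    codons = [dna.residues[i : i + 3] for i in range(0, len(dna.residues), 3)]

    usage: Dict[str, int] = {}
    events: List[Tuple[int, int, str]] = []
    total = 0
    longest = current = 0
    i = 0
    n = len(peptide)
    while i < n:
        if peptide[i] == target:
            total += 1
            usage[codons[i]] = usage.get(codons[i], 0) + 1
            current += 1
            longest = max(longest, current)
            i += 1
        else:
            j = i
            while j < n and peptide[j] != target:
                j += 1
            events.append((i + 1, j, peptide[i:j]))
            current = 0
            i = j
    return RepeatCodonSummary(
        target=target,
        total_target=total,
        interruption_events=tuple(events),
        codon_usage=usage,
        longest_pure_run=longest,
    )
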