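"""Tandem-duplication detection in protein sequences.

Finds adjacent duplicated units such as the pathogenic dup21
(ARPA-PGCPRPA-PGCPRPA-CEPV, a 7-residue / 21-bp unit) and dup9
(PARR-SGR-SGR-GGGG, 3 residues / 9 bp) variants of ATXN2. A reported
array is a maximal periodic run whose primitive period lies in the
requested unit-length range; among the equivalent phases of one run the
end-aligned (rightmost) phase is reported, which is the phase in which
the duplicated exon segments of the known pathogenic variants are
conventionally written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .io import AlphabetError, SequenceRecord


@dataclass(frozen=True)
class TandemDuplication:
    """A maximal tandem array of a primitive unit (1-based coordinates)."""

    sequence_id: str
    unit: str
    start: int
    copies: int

    @property
    def unit_len_aa(self) -> int:
        return len(self.unit)

    @property
    def unit_len_nt(self) -> int:
        """Length of the encoding DNA, for comparison with bp phrasing."""
        return 3 * len(self.unit)

    @property
    def end(self) -> int:
        return self.start + self.copies * len(self.unit) - 1


def _is_primitive(unit: str) -> bool:
    """True if ``unit`` is not itself a repetition of a shorter string."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def find_tandem_duplications(
    record: SequenceRecord, min_unit: int = 2, max_unit: int = 12
) -> List[TandemDuplication]:
    """Find all maximal tandem arrays with primitive unit length in range.

    For each period ``u`` the maximal periodic runs (intervals where
    ``s[i] == s[i+u]`` cannot be extended either way) of length >= 2u are
    located; each contributes one array of ``floor(len/u)`` copies,
    end-aligned within the run. Runs whose primitive period differs from
    ``u`` are reported once, under the primitive period; period-1 arrays
    (homopolymers) are excluded whenever ``min_unit >= 2``. Output is
    sorted by start, then unit length.
    """
    if record.alphabet != "protein":
        raise AlphabetError(
            f"find_tandem_duplications requires a protein record, got {record.alphabet}"
        )
    if min_unit < 1 or max_unit < min_unit:
        raise ValueError("require 1 <= min_unit <= max_unit")
    s = record.residues
    n = len(s)
    out: List[TandemDuplication] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        i = 0
        while i + 2 * u <= n:
            if s[i] != s[i + u]:
                i += 1
                continue
            # extend the periodic match region starting at i
            j = i
            while j + u < n and s[j] == s[j + u]:
                j += 1
            run_start, run_end = i, j + u - 1  # inclusive, 0-based
            run_len = run_end - run_start + 1
            copies = run_len // u
            if copies >= 2:
                start0 = run_end - copies * u + 1  # rightmost phase
                unit = s[start0 : start0 + u]
                if _is_primitive(unit):
                    out.append(
                        TandemDuplication(
                            sequence_id=record.id,
                            unit=unit,
                            start=start0 + 1,
                            copies=copies,
                        )
                    )
            i = j + 1
    out.sort(key=lambda d: (d.start, d.unit_len_aa))
    return out


def brute_force_tandem(
    seq: str, min_unit: int = 2, max_unit: int = 12
) -> List[Tuple[str, int, int]]:
    """Reference O(n^2 u) scanner over all (position, unit length) pairs.

    Returns (unit, 1-based start, copies) triples under the same
    conventions (primitive unit, maximal copies, end-aligned phase:
    the array can be extended neither right by one period position nor
    left by a full copy without breaking periodicity).
    """
    n = len(seq)
    found = []
    for u in range(min_unit, max_unit + 1):
        for i in range(0, n - 2 * u + 1):
            unit = seq[i : i + u]
            if not _is_primitive(unit):
                continue
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k < 2:
                continue
            # end-aligned: next period position must break
            j = i + k * u
            if j < n and seq[j] == seq[j - u]:
                continue
            # not preceded by a further full copy (would not be maximal)
            if i >= u and seq[i - u : i] == unit:
                continue
            found.append((unit, i + 1, k))
    found.sort(key=lambda t: (t[1], len(t[0])))
    return found
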