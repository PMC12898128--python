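"""Homopolymer repeat detection in protein sequences.

Detects tracts of a single target residue (polyQ, polyA, polyP, polyS,
polyG by default) that may be broken by short interruption runs, the way
the polyQ domain of ATXN2 is broken by Pro, His or Ala residues. A tract
is seeded on a pure run of the target residue and greedily merged with
neighboring target runs across interruptions of bounded length; tract size
is counted in target residues only, matching the convention by which a
"73Q" domain means 73 glutamines regardless of its interrupting residues.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .io import AlphabetError, SequenceRecord

#: sentinel flank values for tracts touching a sequence terminus
LEFT_TERMINUS = "^"
RIGHT_TERMINUS = "$"


@dataclass(frozen=True)
class RepeatConfig:
    """Detection thresholds.

    target_residues: residues for which tracts are called (each scanned
        independently; overlapping calls for distinct targets are allowed).
    seed_min: minimal pure run that can seed a tract.
    max_gap: maximal length of one interruption run.
    min_total: minimal number of target residues for a tract to be reported
        (counts the target only, never the interrupting residues).
    """

    target_residues: frozenset = frozenset("QAPSG")
    seed_min: int = 3
    max_gap: int = 2
    min_total: int = 6

    def __post_init__(self) -> None:
        if self.seed_min < 1:
            raise ValueError("seed_min must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_total < self.seed_min:
            raise ValueError("min_total must be >= seed_min")


@dataclass(frozen=True)
class RepeatCall:
    """One detected homopolymer tract (1-based inclusive coordinates)."""

    sequence_id: str
    target_residue: str
    start: int
    end: int
    count_target: int
    interruptions: Tuple[Tuple[int, str], ...]  # (1-based start, run string)
    left_flank: str
    right_flank: str

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def purity(self) -> float:
        return self.count_target / self.width


def _target_runs(seq: str, target: str) -> List[Tuple[int, int]]:
    """0-based half-open spans of maximal runs of ``target`` in ``seq``."""
    return [m.span() for m in re.finditer(re.escape(target) + "+", seq)]


def find_repeats(record: SequenceRecord, config: RepeatConfig = RepeatConfig()) -> List[RepeatCall]:
    """Find all maximal interrupted homopolymer tracts in a protein record.

    For each target residue, maximal pure runs are chained whenever the
    non-target run separating them is at most ``max_gap`` long. A chain is
    reported when it contains at least one seed run (>= ``seed_min``) and
    at least ``min_total`` target residues overall. Chains are maximal: no
    reported call can absorb a further neighboring run without exceeding
    ``max_gap``. Calls are sorted by start, then target residue.
    """
    if record.alphabet != "protein":
        raise AlphabetError(f"find_repeats requires a protein record, got {record.alphabet}")
    seq = record.residues
    calls: List[RepeatCall] = []
    for target in sorted(config.target_residues):
        runs = _target_runs(seq, target)
        i = 0
        while i < len(runs):
            # grow a chain of target runs connected by short gaps
            j = i
            while (
                j + 1 < len(runs)
                and runs[j + 1][0] - runs[j][1] <= config.max_gap
            ):
                j += 1
            chain = runs[i : j + 1]
            count = sum(hi - lo for lo, hi in chain)
            has_seed = any(hi - lo >= config.seed_min for lo, hi in chain)
            if has_seed and count >= config.min_total:
                lo, hi = chain[0][0], chain[-1][1]
                interruptions = tuple(
                    (a_hi + 1, seq[a_hi:b_lo])
                    for (a_lo, a_hi), (b_lo, b_hi) in zip(chain, chain[1:])
                )
                calls.append(
                    RepeatCall(
                        sequence_id=record.id,
                        target_residue=target,
                        start=lo + 1,
                        end=hi,
                        count_target=count,
                        interruptions=interruptions,
                        left_flank=seq[lo - 1] if lo > 0 else LEFT_TERMINUS,
                        right_flank=seq[hi] if hi < len(seq) else RIGHT_TERMINUS,
                    )
                )
            i = j + 1
    calls.sort(key=lambda c: (c.start, c.target_residue))
    return calls


@dataclass
class ResidueFrequencyReport:
    """Ranked residue-frequency tables for flanks and interruptions.

    Each table is a list of (residue, count) sorted by count descending,
    alphabetical within ties. Terminus sentinels are tallied separately
    (``n_left_terminus`` / ``n_right_terminus``) and excluded from the
    ranked tables. Interruption counts are per residue: a "PP" run
    contributes 2 to P.
    """

    left_flank: List[Tuple[str, int]] = field(default_factory=list)
    right_flank: List[Tuple[str, int]] = field(default_factory=list)
    interruptions: List[Tuple[str, int]] = field(default_factory=list)
    n_left_terminus: int = 0
    n_right_terminus: int = 0


def _ranked(counter: Counter) -> List[Tuple[str, int]]:
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def flank_interruption_stats(calls: Sequence[RepeatCall]) -> ResidueFrequencyReport:
    """Aggregate flank and interrupting-residue frequencies over calls."""
    left: Counter = Counter()
    right: Counter = Counter()
    inter: Counter = Counter()
    n_left_term = n_right_term = 0
    for call in calls:
        if call.left_flank == LEFT_TERMINUS:
            n_left_term += 1
        else:
            left[call.left_flank] += 1
        if call.right_flank == RIGHT_TERMINUS:
            n_right_term += 1
        else:
            right[call.right_flank] += 1
        for _, run in call.interruptions:
            inter.update(run)
    return ResidueFrequencyReport(
        left_flank=_ranked(left),
        right_flank=_ranked(right),
        interruptions=_ranked(inter),
        n_left_terminus=n_left_term,
        n_right_terminus=n_right_term,
    )


def brute_force_pure_runs(seq: str, target: str, min_total: int) -> List[Tuple[int, int, int]]:
    """Reference scanner: maximal pure runs of ``target`` with length >= min_total.

    Returns (start, end, count) with 1-based inclusive coordinates. This is
    the oracle against which ``find_repeats`` with ``max_gap=0`` is checked.
    """
    out = []
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] == target:
            j = i
            while j < n and seq[j] == target:
                j += 1
            if j - i >= min_total:
                out.append((i + 1, j, j - i))
            i = j
        else:
            i += 1
    return out
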