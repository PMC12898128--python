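"""Degenerate short-linear-motif scanning with a case-encoded consensus.

PAM2-type motifs are written as consensus strings in which uppercase
letters mark strongly conserved positions, lowercase letters weakly
conserved ones and ``.`` positions carry no information (e.g.
``pksksKLNPNAKpFsLNiNAKeF``). A window is scored as the weighted fraction
of matching positions: uppercase positions carry ``weight_high``,
lowercase ``weight_low`` and ``.`` zero. Matching is case-insensitive, so
scores are invariant to the case of the scanned sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from .io import SequenceRecord

logger = logging.getLogger("atx2kit")


@dataclass(frozen=True)
class ConsensusModel:
    """A case-encoded consensus pattern with two conservation tiers."""

    pattern: str
    name: str = "custom"
    weight_high: float = 1.0
    weight_low: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.replace("-", ""))
        if not self.pattern:
            raise ValueError("pattern empty after stripping hyphens")
        if not (0 < self.weight_low <= self.weight_high):
            raise ValueError("require 0 < weight_low <= weight_high")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def total_weight(self) -> float:
        return sum(
            0.0 if c == "." else (self.weight_low if c.islower() else self.weight_high)
            for c in self.pattern
        )


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    score: float
    matched: str


def score_window(window: str, model: ConsensusModel) -> float:
    """Weighted match fraction of one window against the consensus, in [0,1]."""
    if len(window) != len(model.pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(model.pattern)}"
        )
    total = model.total_weight
    if total == 0:
        return 0.0
    got = 0.0
    for w, p in zip(window.upper(), model.pattern):
        if p == ".":
            continue
        weight = model.weight_low if p.islower() else model.weight_high
        if w == p.upper():
            got += weight
    return got / total


def scan(
    record: SequenceRecord, model: ConsensusModel, threshold: float = 0.60
) -> List[MotifHit]:
    """All windows scoring >= threshold, sorted by start; overlaps allowed."""
    seq = record.residues
    m = len(model.pattern)
    if len(seq) < m:
        logger.warning(
            "record %r shorter than pattern %r (%d < %d): no windows",
            record.id, model.name, len(seq), m,
        )
        return []
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        s = score_window(window, model)
        if s >= threshold:
            hits.append(
                MotifHit(sequence_id=record.id, start=i + 1, end=i + m, score=s, matched=window)
            )
    return hits


# ---------------------------------------------------------------------------
# shipped presets

#: full-length degenerate PAM2 consensus of low-organism Ataxin-2 members
PAM2_FULL_23 = ConsensusModel("pksksKLNPNAKpFsLNiNAKeF", name="PAM2_FULL_23")

#: land-plant variant with the core repeated in tandem (19+ residues)
PAM2_PLANT_TANDEM = ConsensusModel("sekstLNPNAKEFk-LNPNAKSFtps", name="PAM2_PLANT_TANDEM")

#: hand-curated degenerate core distilled from trypanosomatid PAM2
#: precursor candidates; a design choice of this package, not a database
#: consensus
PAM2_CORE_10 = ConsensusModel("lNPnAtpFvP", name="PAM2_CORE_10")

PRESETS = {m.name: m for m in (PAM2_FULL_23, PAM2_PLANT_TANDEM, PAM2_CORE_10)}
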