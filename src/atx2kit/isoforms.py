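"""Internal translation-start (Met) enumeration and isoform classification.

Every methionine in a protein is a candidate internal translation start;
the resulting N-terminally truncated isoform retains, truncates or loses
each annotated domain depending on where the Met falls. Candidates are
binned into zones delimited by the core Ataxin-2 landmarks (LSm, LSmAD,
PAM2, in that canonical order): before the first landmark, within one, or
in the inter-landmark gaps. When a landmark is not annotated its two
flanking zones merge, and zone names always reflect the nearest annotated
landmarks (e.g. ``LSm_to_PAM2`` when LSmAD is missing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .io import DomainAnnotation, SequenceRecord, ValidationError

#: canonical landmark order for the Ataxin-2 family
CORE_ORDER = ("LSm", "LSmAD", "PAM2")


@dataclass(frozen=True)
class IsoformCandidate:
    protein_id: str
    met_position: int  # 1-based
    length_aa: int  # residues from the Met to the C-terminus
    retained_domains: Tuple[Tuple[str, str], ...]  # (label, full|truncated|lost)
    zone: str


def _domain_status(met: int, dom: DomainAnnotation) -> str:
    # a Met exactly at the domain start still yields the full domain
    if met <= dom.start:
        return "full"
    if met <= dom.end:
        return "truncated"
    return "lost"


def _zone_names(cores: Sequence[DomainAnnotation]) -> List[str]:
    """Alternating zone names pre/within/between/post for present landmarks."""
    labels = [d.label for d in cores]
    names = [f"pre_{labels[0]}"] if labels else ["whole"]
    for i, lab in enumerate(labels):
        names.append(f"within_{lab}")
        if i + 1 < len(labels):
            names.append(f"{lab}_to_{labels[i + 1]}")
    if labels:
        names.append(f"post_{labels[-1]}")
    return names


def _zone_of(met: int, cores: Sequence[DomainAnnotation]) -> str:
    if not cores:
        return "whole"
    labels = [d.label for d in cores]
    if met < cores[0].start:
        return f"pre_{labels[0]}"
    for i, dom in enumerate(cores):
        if dom.start <= met <= dom.end:
            return f"within_{dom.label}"
        if i + 1 < len(cores) and dom.end < met < cores[i + 1].start:
            return f"{dom.label}_to_{labels[i + 1]}"
    return f"post_{labels[-1]}"


def enumerate_isoforms(
    record: SequenceRecord,
    domains: Sequence[DomainAnnotation],
    core_labels: Sequence[str] = CORE_ORDER,
) -> List[IsoformCandidate]:
    """One candidate per Met residue, in position order.

    ``domains`` must belong to the record and lie within its bounds. Zone
    computation uses only the domains whose label is in ``core_labels``,
    ordered by start position.
    """
    n = len(record.residues)
    for dom in domains:
        if dom.end > n:
            raise ValidationError(
                f"domain {dom.label!r} ({dom.start}..{dom.end}) exceeds "
                f"record {record.id!r} length {n}"
            )
    cores = sorted(
        (d for d in domains if d.label in core_labels), key=lambda d: d.start
    )
    candidates = []
    for i, residue in enumerate(record.residues):
        if residue != "M":
            continue
        met = i + 1
        statuses = tuple((d.label, _domain_status(met, d)) for d in domains)
        candidates.append(
            IsoformCandidate(
                protein_id=record.id,
                met_position=met,
                length_aa=n - met + 1,
                retained_domains=statuses,
                zone=_zone_of(met, cores),
            )
        )
    return candidates


def zone_census(candidates: Sequence[IsoformCandidate]) -> Dict[str, int]:
    """Zone -> candidate count; counts sum to the number of candidates."""
    return dict(Counter(c.zone for c in candidates))
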