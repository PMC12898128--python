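"""Ortholog-candidate tier classification and iterative consensus search.

An offline implementation of the LSmAD-anchored ortholog search logic:
hits from tabular BLAST files are stratified into quality tiers by the
E-value of their LSmAD evidence (the family-defining domain) and the
presence of supporting domain hits, a column-majority consensus of the
current tier-1 members is rebuilt, and the search is iterated with that
consensus as the new query until the tier-1 set reaches a fixpoint.

Search and sequence-fetch backends are injected callables, so the loop is
fully testable offline; by convention a backend emits hits whose
``query_id`` is the domain label the hit supports (``LSmAD``, ``LSm``,
``PAM2``), which is how labelled multi-domain queries are represented in
a single hit table.

Tier rules (both thresholds printed in the survey are used: strict
1e-10 for high-significance family membership, loose 5e-7 for marginal
homology):

=======  ==========================================================
tier1    LSmAD E-value <= strict AND >= 1 supporting-domain hit
tier2    LSmAD E-value <= strict, no supporting hit
tier3    strict < LSmAD E-value <= loose
rejected no LSmAD hit, E-value > loose, or taxonomy-filtered
=======  ==========================================================
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .io import BlastHit


@dataclass(frozen=True)
class TierConfig:
    strict_threshold: float = 1e-10
    loose_threshold: float = 5e-7
    anchor_label: str = "LSmAD"
    supporting_labels: frozenset = frozenset(("LSm", "PAM2"))
    taxonomy_include: frozenset = frozenset()
    taxonomy_exclude: frozenset = frozenset()
    max_iter: int = 10

    def __post_init__(self) -> None:
        if self.strict_threshold > self.loose_threshold:
            raise ValueError("strict_threshold must be <= loose_threshold")


@dataclass(frozen=True)
class TierAssignment:
    subject_id: str
    tier: str  # tier1 | tier2 | tier3 | rejected
    evidence: Tuple[Tuple[str, float], ...]  # (domain label, best evalue)
    taxonomy_ok: bool


def assign_tiers(
    hits: Sequence[BlastHit],
    query_labels: Mapping[str, str],
    config: TierConfig = TierConfig(),
    taxonomy: Optional[Mapping[str, str]] = None,
) -> List[TierAssignment]:
    """One assignment per distinct subject, from its best per-domain E-values.

    ``query_labels`` maps each hit's query_id to a domain label; an
    unmapped query_id is an error. The result is sorted by subject_id and
    is invariant to the order of the hit rows.
    """
    best: Dict[str, Dict[str, float]] = defaultdict(dict)
    for h in hits:
        if h.query_id not in query_labels:
            raise KeyError(f"query id {h.query_id!r} has no domain label mapping")
        label = query_labels[h.query_id]
        cur = best[h.subject_id].get(label)
        if cur is None or h.evalue < cur:
            best[h.subject_id][label] = h.evalue

    out = []
    for subject in sorted(best):
        evidence = tuple(sorted(best[subject].items()))
        tax_ok = True
        if taxonomy is not None:
            taxon = taxonomy.get(subject)
            if config.taxonomy_include and taxon not in config.taxonomy_include:
                tax_ok = False
            if taxon in config.taxonomy_exclude:
                tax_ok = False
        anchor_e = best[subject].get(config.anchor_label)
        has_support = any(lbl in config.supporting_labels for lbl in best[subject])
        if not tax_ok or anchor_e is None or anchor_e > config.loose_threshold:
            tier = "rejected"
        elif anchor_e <= config.strict_threshold:
            tier = "tier1" if has_support else "tier2"
        else:
            tier = "tier3"
        out.append(TierAssignment(subject, tier, evidence, tax_ok))
    return out


def build_consensus(seqs: Sequence[str]) -> str:
    """Column-wise majority consensus of pre-aligned, equal-length strings.

    Ties break to the alphabetically first residue; the gap character
    ``-`` wins a column only on strict majority, otherwise the most
    common non-gap residue is taken.
    """
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not equal-length (input must be pre-aligned)")
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs)
        gap = counts.get("-", 0)
        if gap * 2 > sum(counts.values()):
            cols.append("-")
            continue
        counts.pop("-", None)
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        cols.append(best)
    return "".join(cols)


@dataclass
class BootstrapResult:
    assignments: List[TierAssignment]
    iterations: int
    converged: bool
    final_query: str


def bootstrap_iterate(
    seed_query: str,
    search: Callable[[str], Sequence[BlastHit]],
    fetch: Callable[[str], str],
    config: TierConfig = TierConfig(),
) -> BootstrapResult:
    """Iterate search -> tier assignment -> tier-1 consensus to a fixpoint.

    The fixpoint criterion is an identical tier-1 subject-id set in two
    consecutive iterations; ``iterations`` counts the completed
    search/consensus rounds before the confirming search. Backend
    exceptions are re-raised annotated with the iteration index. With a
    deterministic backend the whole loop is reproducible bit-exactly.
    """
    query = seed_query
    prev_tier1: Optional[Set[str]] = None
    assignments: List[TierAssignment] = []
    for iteration in range(1, config.max_iter + 1):
        try:
            hits = list(search(query))
        except Exception as exc:
            raise RuntimeError(f"search backend failed at iteration {iteration}") from exc
        labels = {h.query_id: h.query_id for h in hits}
        assignments = assign_tiers(hits, labels, config)
        tier1 = {a.subject_id for a in assignments if a.tier == "tier1"}
        if tier1 == prev_tier1:
            return BootstrapResult(assignments, iteration - 1, True, query)
        prev_tier1 = tier1
        if tier1:
            try:
                seqs = [fetch(sid) for sid in sorted(tier1)]
            except Exception as exc:
                raise RuntimeError(f"fetch backend failed at iteration {iteration}") from exc
            query = build_consensus(seqs)
    return BootstrapResult(assignments, config.max_iter, False, query)
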