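"""Domain-architecture classification and category enrichment.

The canonical Ataxin-2 architecture is the LSm-LSmAD-PAM2 core embedded
in IDRs with no further domains; the family itself is defined by the
LSmAD domain. A protein carrying an extra annotated domain entirely
before the first core domain is an N-terminal chimera, entirely after the
last core domain a C-terminal chimera; extras overlapping or between the
core domains make the layout irregular. Architectures with LSmAD but an
incomplete core are "partial". Unusually long proteins (> 1000 residues
by default) are flagged, since long orthologs are where extra fused
domains were observed.

Functional-category enrichment among chimeric extra domains is tested per
category with the two-sided Fisher exact test (sum of tables with
probability <= that of the observed table), Benjamini-Hochberg adjusted
across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from scipy import stats

from .io import DomainAnnotation


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    length_aa: int
    core_present: frozenset
    core_in_order: bool
    extras: Tuple[Tuple[str, str], ...]  # (label, side in {N, C, internal})
    verdict: str  # canonical | partial | chimeric_N | chimeric_C | chimeric_both | irregular
    unusual_length: bool


#: canonical start order of the core domains
_CORE_RANK = {"LSm": 0, "LSmAD": 1, "PAM2": 2}


def classify_architecture(
    protein_id: str,
    record_length: int,
    domains: Sequence[DomainAnnotation],
    core_labels: frozenset = frozenset(("LSm", "LSmAD", "PAM2")),
    family_anchor: str = "LSmAD",
    long_threshold: int = 1000,
) -> ArchitectureCall:
    """Classify one protein's domain layout.

    The verdict is invariant to the order of the input rows. The family
    anchor domain (LSmAD) must be present for any verdict beyond partial.
    """
    cores = sorted((d for d in domains if d.label in core_labels), key=lambda d: d.start)
    extras_doms = sorted((d for d in domains if d.label not in core_labels), key=lambda d: d.start)
    core_present = frozenset(d.label for d in cores)

    ranks = [_CORE_RANK.get(d.label, 99) for d in cores]
    core_in_order = ranks == sorted(ranks)

    extras: List[Tuple[str, str]] = []
    if cores:
        first_start = cores[0].start
        last_end = cores[-1].end
        for x in extras_doms:
            if x.end < first_start:
                side = "N"
            elif x.start > last_end:
                side = "C"
            else:
                side = "internal"
            extras.append((x.label, side))
    else:
        extras = [(x.label, "internal") for x in extras_doms]

    sides = {side for _, side in extras}
    if not cores:
        verdict = "irregular"
    elif family_anchor not in core_present:
        # the family-defining domain is absent: at most a partial layout
        verdict = "partial" if "internal" not in sides else "irregular"
    elif "internal" in sides or not core_in_order:
        verdict = "irregular"
    elif "N" in sides and "C" in sides:
        verdict = "chimeric_both"
    elif "N" in sides:
        verdict = "chimeric_N"
    elif "C" in sides:
        verdict = "chimeric_C"
    elif core_present == core_labels:
        verdict = "canonical"
    else:
        verdict = "partial"

    return ArchitectureCall(
        protein_id=protein_id,
        length_aa=record_length,
        core_present=core_present,
        core_in_order=core_in_order,
        extras=tuple(extras),
        verdict=verdict,
        unusual_length=record_length > long_threshold,
    )


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    count_in_chimeras: int
    total_chimera_extras: int
    count_in_background: int
    total_background: int
    p_value: float
    q_value: float


def enrich_categories(
    calls: Sequence[ArchitectureCall],
    category_map: Mapping[str, str],
    background: Mapping[str, int],
) -> List[CategoryEnrichment]:
    """Category enrichment among the extra domains of chimeric calls.

    Each observed category is tested in a 2x2 table (category vs rest,
    chimera extras vs background counts) with the two-sided Fisher exact
    test; q-values are Benjamini-Hochberg across the observed categories.
    Unmapped extra labels fall into category ``"other"``.
    """
    if not background:
        raise ValueError("empty background")
    chimera_cats: Dict[str, int] = {}
    for call in calls:
        if not call.verdict.startswith("chimeric"):
            continue
        for label, side in call.extras:
            if side in ("N", "C"):
                cat = category_map.get(label, "other")
                chimera_cats[cat] = chimera_cats.get(cat, 0) + 1
    total_chim = sum(chimera_cats.values())
    if total_chim == 0:
        return []
    total_bg = sum(background.values())

    rows = []
    for cat in sorted(chimera_cats):
        a = chimera_cats[cat]
        c = background.get(cat, 0)
        table = [[a, total_chim - a], [c, total_bg - c]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((cat, a, c, float(p)))

    pvals = [r[3] for r in rows]
    qvals = stats.false_discovery_control(pvals, method="bh")
    out = [
        CategoryEnrichment(
            category=cat,
            count_in_chimeras=a,
            total_chimera_extras=total_chim,
            count_in_background=c,
            total_background=total_bg,
            p_value=p,
            q_value=float(q),
        )
        for (cat, a, c, p), q in zip(rows, qvals)
    ]
    # rank by significance; at equal p (e.g. the two-category case, where
    # enrichment of one category and depletion of the other give the same
    # two-sided table) the over-represented category comes first
    def _excess(r: CategoryEnrichment) -> float:
        return r.count_in_chimeras / r.total_chimera_extras - r.count_in_background / r.total_background

    # p compared at 12 significant digits so float noise cannot mask a tie
    out.sort(key=lambda r: (float(f"{r.p_value:.12g}"), -_excess(r), r.category))
    return out


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table (with a small
    relative tolerance for float ties). Independent reference for tests.
    """
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def prob(x: int) -> float:
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)
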