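#!/usr/bin/env python
"""Tier a synthetic hit table and demonstrate the consensus bootstrap.

Generates a seeded BLAST-style hit table with planted E-value strata,
assigns ortholog-candidate quality tiers, verifies them against the
generator's truth, and runs the consensus bootstrap loop against a
deterministic in-memory search backend in which the round-1 consensus
recruits further family members. Assembles all tables into one cohort
report under results/. Writes results/tier_assignments.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from atx2kit.io import BlastHit
from atx2kit.report import build_report
from atx2kit.simulate import gen_blast_strata
from atx2kit.tiers import TierConfig, assign_tiers, bootstrap_iterate

OUT = Path(__file__).resolve().parents[1] / "results"


def _hit(label, subject, evalue):
    return BlastHit(label, subject, 50.0, 70, 10, 0, 1, 70, 1, 70, evalue, 100.0)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    hits, truth = gen_blast_strata(seed=args.seed)
    assignments = assign_tiers(hits, {h.query_id: h.query_id for h in hits})
    df = pd.DataFrame(
        dict(subject_id=a.subject_id, tier=a.tier,
             evidence=";".join(f"{l}:{e:.2g}" for l, e in a.evidence),
             truth=truth[a.subject_id])
        for a in assignments
    )
    agreement = (df.tier == df.truth).mean()

    # deterministic two-round bootstrap fixture: the seed query sees only
    # the near members; their consensus also matches the distant one
    members = {"near1": "QQPAGLS", "near2": "QQPAGLS", "far1": "QAPAGLS"}

    def search(query):
        found = ["near1", "near2"] if query == "SEED" else list(members)
        return [_hit("LSmAD", s, 1e-15) for s in found] + [_hit("LSm", s, 1e-6) for s in found]

    result = bootstrap_iterate("SEED", search, members.__getitem__, TierConfig())

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "tier_assignments.tsv", sep="\t", index=False)
    report = build_report(
        {"tiers": df.drop(columns="truth")},
        config={"strict": 1e-10, "loose": 5e-7},
        seed=args.seed,
    )
    report.to_tsv_dir(OUT / "cohort_report")

    print(df.tier.value_counts().to_string())
    print(f"\nTier agreement with planted strata: {agreement:.1%}")
    print(f"Bootstrap: converged={result.converged} after {result.iterations} "
          f"iterations; tier-1 members: "
          f"{sorted(a.subject_id for a in result.assignments if a.tier == 'tier1')}")
    print(f"Final consensus query: {result.final_query}")


if __name__ == "__main__":
    main()
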