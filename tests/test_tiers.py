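"""Ortholog tier classification, consensus building and bootstrap iteration."""

import pytest

from atx2kit.io import BlastHit
from atx2kit.tiers import (
    BootstrapResult,
    TierConfig,
    assign_tiers,
    bootstrap_iterate,
    build_consensus,
)


def _hit(query, subject, evalue):
    return BlastHit(query, subject, 50.0, 70, 10, 0, 1, 70, 1, 70, evalue, 100.0)


LABELS = {"qLSmAD": "LSmAD", "qLSm": "LSm", "qPAM2": "PAM2"}


class TestAssign:
    def test_anchor_plus_support_is_tier1(self):
        hits = [_hit("qLSmAD", "s1", 1e-12), _hit("qLSm", "s1", 1e-5)]
        (a,) = assign_tiers(hits, LABELS)
        assert a.tier == "tier1"
        assert dict(a.evidence) == {"LSmAD": 1e-12, "LSm": 1e-5}

    def test_anchor_alone_strict_is_tier2(self):
        (a,) = assign_tiers([_hit("qLSmAD", "s1", 1e-12)], LABELS)
        assert a.tier == "tier2"

    def test_anchor_between_thresholds_is_tier3(self):
        (a,) = assign_tiers([_hit("qLSmAD", "s1", 1e-8)], LABELS)
        assert a.tier == "tier3"

    def test_anchor_above_loose_rejected(self):
        (a,) = assign_tiers([_hit("qLSmAD", "s1", 1e-3)], LABELS)
        assert a.tier == "rejected"

    def test_support_without_anchor_rejected(self):
        (a,) = assign_tiers([_hit("qLSm", "s1", 1e-30)], LABELS)
        assert a.tier == "rejected"

    def test_best_evalue_per_domain_used(self):
        hits = [_hit("qLSmAD", "s1", 1e-3), _hit("qLSmAD", "s1", 1e-20)]
        (a,) = assign_tiers(hits, LABELS)
        assert a.tier == "tier2"
        assert dict(a.evidence)["LSmAD"] == 1e-20

    def test_taxonomy_exclusion_rejects(self):
        cfg = TierConfig(taxonomy_exclude=frozenset({"bacteria"}))
        hits = [_hit("qLSmAD", "s1", 1e-12), _hit("qLSmAD", "s2", 1e-12)]
        out = assign_tiers(hits, LABELS, cfg, taxonomy={"s1": "bacteria", "s2": "metazoa"})
        by_id = {a.subject_id: a for a in out}
        assert by_id["s1"].tier == "rejected" and not by_id["s1"].taxonomy_ok
        assert by_id["s2"].tier == "tier2" and by_id["s2"].taxonomy_ok

    def test_taxonomy_include_list(self):
        cfg = TierConfig(taxonomy_include=frozenset({"metazoa"}))
        out = assign_tiers([_hit("qLSmAD", "s1", 1e-12)], LABELS, cfg, taxonomy={"s1": "plantae"})
        assert out[0].tier == "rejected"

    def test_unmapped_query_errors(self):
        with pytest.raises(KeyError, match="mystery"):
            assign_tiers([_hit("mystery", "s1", 1e-12)], LABELS)

    def test_row_order_invariance(self):
        hits = [
            _hit("qLSmAD", "s1", 1e-12), _hit("qLSm", "s1", 1e-5),
            _hit("qLSmAD", "s2", 1e-8), _hit("qLSmAD", "s3", 1.0),
        ]
        assert assign_tiers(hits, LABELS) == assign_tiers(list(reversed(hits)), LABELS)

    def test_tightening_strict_never_promotes(self):
        hits = [
            _hit("qLSmAD", "s1", 1e-12), _hit("qLSm", "s1", 1e-5),
            _hit("qLSmAD", "s2", 1e-11), _hit("qLSmAD", "s3", 1e-8),
        ]
        order = {"tier1": 3, "tier2": 2, "tier3": 1, "rejected": 0}
        loosecfg = TierConfig(strict_threshold=1e-10)
        tightcfg = TierConfig(strict_threshold=1e-13)
        loose = {a.subject_id: order[a.tier] for a in assign_tiers(hits, LABELS, loosecfg)}
        tight = {a.subject_id: order[a.tier] for a in assign_tiers(hits, LABELS, tightcfg)}
        assert all(tight[s] <= loose[s] for s in loose)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TierConfig(strict_threshold=1e-5, loose_threshold=1e-10)

    def test_planted_strata_recovered(self):
        from atx2kit.simulate import gen_blast_strata

        hits, truth = gen_blast_strata(seed=2)
        labels = {h.query_id: h.query_id for h in hits}
        out = assign_tiers(hits, labels)
        assert {a.subject_id: a.tier for a in out} == truth


class TestConsensus:
    def test_column_majority(self):
        assert build_consensus(["QQP", "QQP", "QAP"]) == "QQP"

    def test_single_sequence(self):
        assert build_consensus(["MSLK"]) == "MSLK"

    def test_tie_breaks_alphabetical(self):
        assert build_consensus(["AB", "BA"]) == "AA"

    def test_gap_needs_strict_majority(self):
        assert build_consensus(["A-", "A-", "AQ"]) == "A-"
        assert build_consensus(["A-", "AQ"]) == "AQ"

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            build_consensus(["AB", "ABC"])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_consensus([])


def _backend_hits(subjects, evalue=1e-12, support=True):
    hits = []
    for s in subjects:
        hits.append(_hit("LSmAD", s, evalue))
        if support:
            hits.append(_hit("LSm", s, 1e-6))
    return hits


class TestBootstrap:
    SEQS = {"s1": "QQPA", "s2": "QQPA", "s3": "QAPA"}

    def test_constant_backend_fixpoint_after_one_round(self):
        result = bootstrap_iterate(
            "QQPA", lambda q: _backend_hits(["s1", "s2"]), self.SEQS.__getitem__
        )
        assert result.converged and result.iterations == 1
        assert {a.subject_id for a in result.assignments if a.tier == "tier1"} == {"s1", "s2"}

    def test_two_round_recruitment(self):
        """The round-1 consensus recruits the remaining member; fixpoint at round 3."""

        def search(query):
            if query == "SEED":
                return _backend_hits(["s1", "s2"])
            return _backend_hits(["s1", "s2", "s3"])  # consensus finds everyone

        result = bootstrap_iterate("SEED", search, self.SEQS.__getitem__)
        assert result.converged and result.iterations == 2
        assert {a.subject_id for a in result.assignments if a.tier == "tier1"} == {"s1", "s2", "s3"}
        assert result.final_query == "QQPA"  # majority of s1,s2,s3

    def test_oscillating_backend_never_converges(self):
        state = {"flip": False}

        def search(query):
            state["flip"] = not state["flip"]
            return _backend_hits(["s1"] if state["flip"] else ["s2"])

        result = bootstrap_iterate("SEED", search, self.SEQS.__getitem__, TierConfig(max_iter=6))
        assert not result.converged
        assert result.iterations == 6

    def test_deterministic_backend_reproducible(self):
        def search(query):
            return _backend_hits(["s1", "s3"])

        r1 = bootstrap_iterate("SEED", search, self.SEQS.__getitem__)
        r2 = bootstrap_iterate("SEED", search, self.SEQS.__getitem__)
        assert r1 == r2

    def test_backend_failure_annotated_with_iteration(self):
        def search(query):
            raise OSError("backend down")

        with pytest.raises(RuntimeError, match="iteration 1"):
            bootstrap_iterate("SEED", search, self.SEQS.__getitem__)
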