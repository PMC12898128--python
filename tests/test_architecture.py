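"""Architecture classification and category enrichment."""

import itertools

import pytest
from hypothesis import given, strategies as st

from atx2kit.architecture import (
    classify_architecture,
    enrich_categories,
    fisher_two_sided_oracle,
)
from atx2kit.io import DomainAnnotation


def _doms(pid, spans):
    return [DomainAnnotation(pid, label, s, e) for label, s, e in spans]


class TestClassify:
    def test_n_terminal_chimera_with_unusual_length(self):
        """A fused upstream domain on a long protein: the chlorophyte-style fusion."""
        call = classify_architecture(
            "p1", 1200,
            _doms("p1", [("KCS", 10, 300), ("LSm", 400, 478), ("LSmAD", 520, 590), ("PAM2", 800, 813)]),
        )
        assert call.verdict == "chimeric_N"
        assert call.unusual_length is True
        assert call.extras == (("KCS", "N"),)
        assert call.core_in_order

    def test_canonical(self):
        call = classify_architecture(
            "p2", 900, _doms("p2", [("LSm", 300, 377), ("LSmAD", 430, 500), ("PAM2", 700, 713)])
        )
        assert call.verdict == "canonical"
        assert call.unusual_length is False

    def test_partial_without_pam2(self):
        """LSm + LSmAD without PAM2, as in the short trypanosomatid entries."""
        call = classify_architecture("p3", 500, _doms("p3", [("LSm", 50, 127), ("LSmAD", 180, 250)]))
        assert call.verdict == "partial"

    def test_lsmad_absent_is_at_most_partial(self):
        call = classify_architecture(
            "p4", 800, _doms("p4", [("LSm", 50, 127), ("PAM2", 500, 513), ("RRM", 600, 700)])
        )
        assert call.verdict == "partial"

    def test_extra_overlapping_core_is_irregular(self):
        call = classify_architecture(
            "p5", 900,
            _doms("p5", [("LSm", 300, 377), ("LSmAD", 430, 500), ("PAM2", 700, 713), ("HEL", 350, 450)]),
        )
        assert call.extras == (("HEL", "internal"),)
        assert call.verdict == "irregular"

    def test_chimeric_both_sides(self):
        call = classify_architecture(
            "p6", 1400,
            _doms("p6", [("DDX", 10, 200), ("LSm", 300, 377), ("LSmAD", 430, 500),
                         ("PAM2", 700, 713), ("RRM", 900, 1000)]),
        )
        assert call.verdict == "chimeric_both"

    def test_no_domains_is_irregular(self):
        assert classify_architecture("p7", 400, []).verdict == "irregular"

    def test_row_permutation_invariance(self):
        spans = [("PAM2", 700, 713), ("LSmAD", 430, 500), ("KCS", 10, 300), ("LSm", 400, 478)]
        calls = {
            classify_architecture("p8", 1200, _doms("p8", list(perm))).verdict
            for perm in itertools.permutations(spans)
        }
        assert calls == {"chimeric_N"}


class TestFisher:
    def test_matches_hypergeometric_oracle_small_margins(self):
        """scipy two-sided Fisher equals the sum of <=-probability tables."""
        from scipy.stats import fisher_exact

        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-8)

    def test_identical_minimal_proportions(self):
        assert fisher_two_sided_oracle(1, 1, 1, 1) == pytest.approx(1.0)


def _chimera_call(pid, label):
    return classify_architecture(
        pid, 1200,
        _doms(pid, [(label, 10, 200), ("LSm", 300, 377), ("LSmAD", 430, 500), ("PAM2", 700, 713)]),
    )


class TestEnrichment:
    def test_enrichment_p_matches_oracle(self):
        """6/10 chimera extras in one category vs 10/100 background."""
        calls = [_chimera_call(f"c{i}", f"R{i}" if i < 6 else f"X{i}") for i in range(10)]
        category_map = {f"R{i}": "rrna" for i in range(6)}
        category_map.update({f"X{i}": "other" for i in range(6, 10)})
        background = {"rrna": 10, "other": 90}
        rows = enrich_categories(calls, category_map, background)
        rrna = next(r for r in rows if r.category == "rrna")
        assert rrna.count_in_chimeras == 6 and rrna.total_chimera_extras == 10
        assert rrna.p_value == pytest.approx(fisher_two_sided_oracle(6, 4, 10, 90), rel=1e-8)

    def test_unmapped_labels_become_other(self):
        calls = [_chimera_call("c1", "MYSTERY")]
        rows = enrich_categories(calls, {}, {"other": 5, "rrna": 5})
        assert [r.category for r in rows] == ["other"]

    def test_no_chimeras_empty_result(self):
        call = classify_architecture(
            "p", 900, _doms("p", [("LSm", 300, 377), ("LSmAD", 430, 500), ("PAM2", 700, 713)])
        )
        assert enrich_categories([call], {}, {"other": 5}) == []

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            enrich_categories([_chimera_call("c1", "A")], {}, {})

    def test_bh_q_values_monotone_in_p_rank(self):
        calls = [_chimera_call(f"c{i}", l) for i, l in enumerate("AAAABBCD")]
        cmap = {"A": "catA", "B": "catB", "C": "catC", "D": "catD"}
        background = {"catA": 2, "catB": 30, "catC": 30, "catD": 38}
        rows = enrich_categories(calls, cmap, background)
        by_p = sorted(rows, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_value - 1e-12 for r in rows)


class TestCohortRecovery:
    def test_planted_verdicts_recovered_and_fraction_within_binomial_error(self):
        from atx2kit.simulate import ArchitectureCohortSpec, gen_architecture_cohort

        spec = ArchitectureCohortSpec(seed=5, n_proteins=100, chimera_fraction=0.05)
        lengths, domains, cmap, background, truth = gen_architecture_cohort(spec)
        by_protein = {}
        for d in domains:
            by_protein.setdefault(d.protein_id, []).append(d)
        calls = {
            pid: classify_architecture(pid, lengths[pid], by_protein[pid])
            for pid in lengths
        }
        assert {pid: c.verdict for pid, c in calls.items()} == truth
        n_chim = sum(1 for v in truth.values() if v.startswith("chimeric"))
        # 100 draws at rate 0.05: 3 sigma ~ 6.5
        assert abs(n_chim - 5) <= 7

    def test_concentrated_category_ranks_first(self):
        from atx2kit.simulate import ArchitectureCohortSpec, gen_architecture_cohort

        spec = ArchitectureCohortSpec(
            seed=8, n_proteins=200, chimera_fraction=0.15,
            chimera_categories=(("rRNA processing", 0.9), ("other", 0.1)),
            background_categories=(("rRNA processing", 10), ("other", 90)),
        )
        lengths, domains, cmap, background, truth = gen_architecture_cohort(spec)
        by_protein = {}
        for d in domains:
            by_protein.setdefault(d.protein_id, []).append(d)
        calls = [classify_architecture(pid, lengths[pid], by_protein[pid]) for pid in lengths]
        rows = enrich_categories(calls, cmap, background)
        assert rows[0].category == "rRNA processing"
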