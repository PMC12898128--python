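"""Homopolymer tract detection: worked peptides, oracle equivalence, recovery."""

import pytest
from hypothesis import given, strategies as st

from atx2kit.io import AlphabetError, SequenceRecord
from atx2kit.repeats import (
    RepeatCall,
    RepeatConfig,
    brute_force_pure_runs,
    find_repeats,
    flank_interruption_stats,
)
from atx2kit import worked_examples as wx


def test_human_polyq_tract():
    """The 23Q tract of the human N-terminal peptide, Pro-flanked, uninterrupted."""
    rec = SequenceRecord("q99700_156_202", wx.HUMAN_POLYQ_PEPTIDE)
    (call,) = [c for c in find_repeats(rec) if c.target_residue == "Q"]
    assert (call.start, call.end, call.count_target) == (11, 33, 23)
    assert call.interruptions == ()
    assert (call.left_flank, call.right_flank) == ("P", "P")
    assert call.purity == 1.0


def test_no_target_residue_yields_nothing():
    rec = SequenceRecord("a", "AAAA")
    assert find_repeats(rec, RepeatConfig(target_residues=frozenset("Q"))) == []


def test_ostrich_polya_merge_across_single_gln():
    """PolyA analog tract: 7 Ala in two runs bridged by one Gln, reaching the C-terminus."""
    rec = SequenceRecord("ostrich", wx.OSTRICH_POLYA_PEPTIDE)
    cfg = RepeatConfig(target_residues=frozenset("A"), max_gap=1, min_total=6)
    (call,) = find_repeats(rec, cfg)
    assert (call.start, call.end, call.count_target) == (6, 13, 7)
    assert call.interruptions == ((11, "Q"),)
    # residue 5 is the Gln of MSLKQ...; tracts start on the target residue,
    # so the single residue immediately left of the tract is that Gln
    assert (call.left_flank, call.right_flank) == ("Q", "$")


def test_dna_record_rejected():
    with pytest.raises(AlphabetError):
        find_repeats(SequenceRecord("d", "ACGT", alphabet="dna"))


def test_config_validation():
    with pytest.raises(ValueError):
        RepeatConfig(seed_min=0)
    with pytest.raises(ValueError):
        RepeatConfig(min_total=2, seed_min=3)


@given(st.text(alphabet="QPA", min_size=0, max_size=120), st.integers(3, 8))
def test_max_gap_zero_equals_pure_run_oracle(seq, min_total):
    """With no interruptions allowed, calls are exactly the maximal pure runs."""
    rec = SequenceRecord("s", seq) if seq else None
    if rec is None:
        return
    cfg = RepeatConfig(target_residues=frozenset("Q"), max_gap=0, min_total=min_total,
                       seed_min=min(3, min_total))
    calls = find_repeats(rec, cfg)
    oracle = brute_force_pure_runs(seq, "Q", min_total)
    assert [(c.start, c.end, c.count_target) for c in calls] == oracle
    assert all(c.interruptions == () for c in calls)


@given(st.text(alphabet="QPAH", min_size=1, max_size=150), st.integers(0, 3))
def test_conservation_invariant(seq, max_gap):
    """Target count plus interruption residues always equals tract width."""
    rec = SequenceRecord("s", seq)
    cfg = RepeatConfig(target_residues=frozenset("QA"), max_gap=max_gap, min_total=4,
                       seed_min=3)
    for call in find_repeats(rec, cfg):
        inter_len = sum(len(r) for _, r in call.interruptions)
        assert call.count_target + inter_len == call.width
        assert 0 < call.purity <= 1
        assert seq[call.start - 1] == call.target_residue
        assert seq[call.end - 1] == call.target_residue
        assert all(len(r) <= max_gap for _, r in call.interruptions)


def test_output_independent_of_target_set_order():
    rec = SequenceRecord("s", "QQQQQQPPAAAAAA" * 3)
    a = find_repeats(rec, RepeatConfig(target_residues=frozenset("QAPSG")))
    b = find_repeats(rec, RepeatConfig(target_residues=frozenset("GSPAQ")))
    assert a == b


@pytest.mark.parametrize("seed", [1, 7, 23, 101])
def test_planted_tract_recovered_exactly(seed):
    from atx2kit.simulate import PlantedRepeat, RepeatCohortSpec, gen_repeat_cohort

    plant = PlantedRepeat(residue="Q", total=23, interruptions=((8, "P"), (13, "PP")),
                          left_flank="P", right_flank="H")
    spec = RepeatCohortSpec(seed=seed, n_sequences=3, length=200, planted=(plant, plant, None))
    records, truth = gen_repeat_cohort(spec)
    cfg = RepeatConfig(target_residues=frozenset("Q"), max_gap=2, min_total=6)
    for expected in truth:
        rec = next(r for r in records if r.id == expected.sequence_id)
        calls = find_repeats(rec, cfg)
        assert expected in calls


class TestFlankStats:
    def _call(self, left="P", right="P", interruptions=()):
        return RepeatCall("s", "Q", 10, 20, 11 - sum(len(r) for _, r in interruptions),
                          tuple(interruptions), left, right)

    def test_empty(self):
        rep = flank_interruption_stats([])
        assert rep.left_flank == rep.right_flank == rep.interruptions == []

    def test_left_flank_ranking(self):
        calls = [self._call(left=x) for x in "PPH"]
        rep = flank_interruption_stats(calls)
        assert rep.left_flank == [("P", 2), ("H", 1)]

    def test_interruptions_counted_per_residue(self):
        calls = [self._call(interruptions=((12, run),)) for run in ("P", "PP", "H")]
        rep = flank_interruption_stats(calls)
        assert rep.interruptions == [("P", 3), ("H", 1)]

    def test_terminus_sentinels_tallied_separately(self):
        calls = [self._call(left="^", right="$"), self._call(left="P", right="$")]
        rep = flank_interruption_stats(calls)
        assert rep.n_left_terminus == 1 and rep.n_right_terminus == 2
        assert rep.left_flank == [("P", 1)] and rep.right_flank == []

    def test_alphabetical_tie_break(self):
        calls = [self._call(left=x) for x in "HPHP"]
        rep = flank_interruption_stats(calls)
        assert rep.left_flank == [("H", 2), ("P", 2)]
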