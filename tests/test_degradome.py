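"""Degradome tag mapping, cleavage-site scoring and the category rules."""

import math
import random

import pytest

from stagemir.degradome import (CleavageCall, DegradomeTag, TranscriptProfile,
                                analyze_condition, category_tally,
                                classify_category, compare_conditions,
                                find_cleavage_sites, map_tags, score_site,
                                tplot_data)
from stagemir.reference_catalog import SequenceCatalog, reverse_complement

MIR = "TGTGATGTGACGTAGTGGTAC"  # 21 nt


def _profile(abund, length=3000, tid="tx"):
    return TranscriptProfile(tid, length, abundance=dict(abund))


class TestTagValidation:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            DegradomeTag("ACGT" * 4)  # 16 nt
        with pytest.raises(ValueError):
            DegradomeTag("ACGT" * 7)  # 28 nt
        assert DegradomeTag("ACGTACGTACGTACGTACGT").count == 1

    def test_count_positive(self):
        with pytest.raises(ValueError):
            DegradomeTag("ACGTACGTACGTACGTACGT", 0)


class TestMapTags:
    def setup_method(self):
        rng = random.Random(8)
        self.tseq = "".join(rng.choice("ACGT") for _ in range(1000))
        self.tx = SequenceCatalog("cds", {"tx1": self.tseq})

    def test_unmatched_tag_no_profile(self):
        tags = [DegradomeTag("A" * 20, 2)]
        assert map_tags(tags, self.tx) == {}

    def test_count_added_at_five_prime_position(self):
        tag = DegradomeTag(self.tseq[499:519], 3)
        prof = map_tags([tag], self.tx)["tx1"]
        assert prof.abundance[500] == 3

    def test_two_tags_same_start_summed(self):
        t1 = DegradomeTag(self.tseq[499:519], 2)
        t2 = DegradomeTag(self.tseq[499:521], 4)  # same 5' end, longer
        prof = map_tags([t1, t2], self.tx)["tx1"]
        assert prof.abundance[500] == 6

    def test_mass_conservation_single_mapping(self):
        tags = [DegradomeTag(self.tseq[i:i + 20], c)
                for i, c in ((10, 1), (200, 5), (700, 2))]
        profs = map_tags(tags, self.tx)
        assert profs["tx1"].total == 8

    def test_multimapped_flagged_on_both(self):
        shared = self.tseq[100:120]
        tx = SequenceCatalog("cds", {"a": self.tseq, "b": "GG" + shared + "CC" * 20})
        profs = map_tags([DegradomeTag(shared, 1)], tx)
        assert profs["a"].multimapped and profs["b"].multimapped


class TestScoreSite:
    def test_perfect_complement_zero(self):
        assert score_site(MIR, reverse_complement(MIR)) == 0.0

    def test_single_gu_outside_core(self):
        # miRNA position 15 is index 14; make the target base create G:U
        win = list(reverse_complement(MIR))
        k = len(MIR) - 1 - 14  # window index opposite miRNA position 15
        base = MIR[14]
        win[k] = {"G": "T", "T": "G"}.get(base)
        assert win[k] is not None, "choose a miRNA with G/T at position 15"
        assert score_site(MIR, "".join(win)) == pytest.approx(0.5)

    def test_mismatch_at_position_ten_rejected(self):
        win = list(reverse_complement(MIR))
        k = len(MIR) - 1 - 9
        win[k] = "C" if win[k] != "C" else "A"
        if (MIR[9].replace("U", "T"), win[k]) in {("G", "T"), ("T", "G")}:
            win[k] = "A"
        assert score_site(MIR, "".join(win)) == math.inf

    def test_core_penalty_doubled(self):
        win = list(reverse_complement(MIR))
        k = len(MIR) - 1 - 4  # miRNA position 5 (core)
        options = set("ACGT") - {win[k]}
        options -= {{"G": "T", "T": "G"}.get(MIR[4], "")}
        win[k] = sorted(options - {reverse_complement(MIR)[k]})[0]
        assert score_site(MIR, "".join(win)) == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIR, "ACGT")


class TestFindCleavage:
    def _planted(self):
        rng = random.Random(9)
        tseq = list("".join(rng.choice("ACGT") for _ in range(600)))
        w0 = 300
        tseq[w0:w0 + len(MIR)] = reverse_complement(MIR)
        tseq = "".join(tseq)
        cleave = w0 + 1 + len(MIR) - 10  # 1-based position opposite miRNA nt 10
        return tseq, cleave

    def test_planted_site_called(self):
        tseq, cleave = self._planted()
        prof = _profile({cleave: 5}, length=len(tseq))
        calls = find_cleavage_sites("m", MIR, tseq, prof)
        assert [c.cleavage_position for c in calls] == [cleave]
        assert calls[0].alignment_score == 0.0

    def test_zero_abundance_no_call(self):
        tseq, cleave = self._planted()
        prof = _profile({cleave + 50: 5}, length=len(tseq))
        assert find_cleavage_sites("m", MIR, tseq, prof) == []

    def test_score_gate(self):
        tseq, cleave = self._planted()
        prof = _profile({cleave: 5}, length=len(tseq))
        assert find_cleavage_sites("m", MIR, tseq, prof, max_score=-1.0) == []


class TestClassifyCategory:
    @pytest.mark.parametrize("abund,pos,want", [
        ({500: 5, 900: 1, 1200: 1}, 500, 0),
        ({100: 3, 400: 3, 700: 1}, 100, 1),
        ({100: 2, 200: 5, 300: 1, 400: 1}, 100, 2),   # median 1.5
        ({100: 2, 200: 5, 300: 4, 400: 2}, 100, 3),   # median 3, a <= med
        ({100: 1, 200: 5}, 100, 4),
        ({100: 1}, 100, 4),
    ])
    def test_rule_walkthrough(self, abund, pos, want):
        assert classify_category(_profile(abund), pos) == want

    def test_zero_abundance_position_rejected(self):
        with pytest.raises(ValueError):
            classify_category(_profile({100: 2}), 101)

    def test_agrees_with_literal_recheck_on_random_profiles(self):
        """The implementation matches a literal re-check of the five
        stated rules on 10,000 random profiles."""
        from conftest import category_oracle
        rng = random.Random(123)
        for _ in range(10_000):
            k = rng.randint(1, 8)
            positions = rng.sample(range(1, 2000), k)
            abund = {p: rng.choice((1, 1, 1, 2, 2, 3, 5, 8)) for p in positions}
            pos = rng.choice(positions)
            prof = _profile(abund)
            assert classify_category(prof, pos) == category_oracle(abund, pos)


class TestTPlot:
    def test_empty_profile(self):
        assert tplot_data(_profile({}, length=0)) == []

    def test_series_and_flags(self):
        prof = _profile({2: 3, 5: 1, 9: 7}, length=10)
        calls = [CleavageCall("m", "tx", 9, 0.0, 0)]
        series = tplot_data(prof, calls)
        assert len(series) == 10
        nonzero = [(p, a) for p, a, _f in series if a]
        assert nonzero == [(2, 3), (5, 1), (9, 7)]
        assert [p for p, _a, f in series if f] == [9]


class TestCompareConditions:
    def test_pbs_only_target(self):
        calls = {"PBS": [CleavageCall("m", "tx", 100, 0.0, 2)],
                 "SCR": [], "ANTIMIR": []}
        rows = compare_conditions(calls)
        assert rows[0]["categories"] == {"PBS": 2, "SCR": None, "ANTIMIR": None}
        assert rows[0]["representative"] == 2

    def test_identical_inputs_identical_categories(self):
        c = CleavageCall("m", "tx", 100, 0.0, 3)
        rows = compare_conditions({"PBS": [c], "SCR": [c], "ANTIMIR": [c]})
        assert rows[0]["categories"] == {"PBS": 3, "SCR": 3, "ANTIMIR": 3}

    def test_tally(self):
        rows = [{"mirna": "m", "transcript_id": f"t{i}",
                 "categories": {"PBS": c}, "representative": c}
                for i, c in enumerate([4, 4, 2, 0])]
        assert category_tally(rows) == {4: 2, 2: 1, 0: 1}


def test_table5_fixture_round_trip(fixture_tables, tmp_path):
    """Reading and rewriting the curated degradome table is byte-identical."""
    from stagemir.pipeline import write_table5, _fixture_path
    out = tmp_path / "t5.tsv"
    write_table5(fixture_tables.table5, out)
    assert out.read_bytes() == \
        _fixture_path("table5_degradome_targets.tsv").read_bytes()
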