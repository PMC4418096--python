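"""Precursor extraction, hairpin classification, naming and the
known-similarity screen."""

import random

import pytest

from stagemir.novel_discovery import (GenomeLocus, PrecursorCandidate,
                                      check_not_known, classify_hairpin,
                                      discover_novel, extract_precursor,
                                      major_terminal_loops, name_novel)
from stagemir.reference_catalog import SequenceCatalog, reverse_complement

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def hairpin_locus(rng, stem=22, loop=8, flank=75, arm="5p"):
    """A planted hairpin segment with genomic flanks; returns (segment,
    mature_offset, mature)."""
    while True:
        mature = "".join(rng.choices("ACGT", weights=(2, 3, 3, 2), k=stem))
        if mature.count("G") >= 3:
            break
    other = list(reverse_complement(mature))
    cs = [i for i, b in enumerate(other) if b == "C" and 2 < i < len(other) - 3]
    for i in cs[:3]:
        other[i] = "T"
    other = "".join(other)
    lp = "".join(rng.choice("ACGT") for _ in range(loop))
    hp = mature + lp + other if arm == "5p" else other + lp + mature
    f5 = "".join(rng.choice("ACGT") for _ in range(flank))
    f3 = "".join(rng.choice("ACGT") for _ in range(flank))
    seg = f5 + hp + f3
    return seg, seg.find(mature), mature


class TestExtractPrecursor:
    def setup_method(self):
        rng = random.Random(5)
        self.contig = "".join(rng.choice("ACGT") for _ in range(500))
        self.genome = SequenceCatalog("genome", {"c1": self.contig})

    def test_zero_flank_identity(self):
        loc = GenomeLocus("c1", 100, 122)
        cand = extract_precursor(self.genome, loc, flank=0)
        assert cand.precursor_sequence == \
            self.contig[100:122].replace("T", "U")
        assert cand.mature_offset == 0

    def test_mid_contig_window(self):
        loc = GenomeLocus("c1", 200, 222)
        cand = extract_precursor(self.genome, loc, flank=75)
        assert len(cand.precursor_sequence) == 172
        assert cand.mature_offset == 75

    def test_clipped_at_contig_start(self):
        loc = GenomeLocus("c1", 10, 32)
        cand = extract_precursor(self.genome, loc, flank=75)
        assert len(cand.precursor_sequence) == 10 + 22 + 75
        assert cand.mature_offset == 10

    def test_minus_strand_reverse_complemented(self):
        loc = GenomeLocus("c1", 200, 222, "-")
        cand = extract_precursor(self.genome, loc, flank=10)
        expected = reverse_complement(self.contig[190:232]).replace("T", "U")
        assert cand.precursor_sequence == expected
        assert cand.mature_offset == 10

    def test_locus_outside_contig(self):
        with pytest.raises(ValueError):
            extract_precursor(self.genome, GenomeLocus("c1", 490, 520))
        with pytest.raises(KeyError):
            extract_precursor(self.genome, GenomeLocus("c9", 0, 22))


class TestClassifyHairpin:
    def test_planted_hairpin_passes_with_correct_arm(self):
        rng = random.Random(1)
        for arm in ("5p", "3p"):
            for _ in range(5):
                seg, m0, mat = hairpin_locus(rng, arm=arm)
                lo = max(0, m0 - 75)
                window = seg[lo:m0 + len(mat) + 75]
                cand = PrecursorCandidate(None, window.replace("T", "U"),
                                          m0 - lo, len(mat)).fold()
                call = classify_hairpin(cand)
                # flank structure occasionally interferes; most pass
                if call.passed:
                    assert call.arm == arm

    def test_energy_threshold(self):
        # a marginal hairpin fails when the threshold is pushed below it
        seq = ("GCGC" + "A" * 10 + "GCGC").replace("T", "U")
        cand = PrecursorCandidate(None, seq, 0, 4).fold()
        call = classify_hairpin(cand, mfe_threshold=-50.0)
        assert not call.passed and call.reason == "energy"

    def test_two_hairpin_structure_fails_topology(self):
        rng = random.Random(2)
        seg1, m0, mat = hairpin_locus(rng, flank=5)
        seg2, _m, _s = hairpin_locus(rng, flank=5)
        seq = (seg1 + "AAAAAA" + seg2).replace("T", "U")
        cand = PrecursorCandidate(None, seq, m0, len(mat)).fold()
        call = classify_hairpin(cand)
        assert not call.passed
        assert "terminal loops" in call.reason

    def test_mature_outside_precursor_rejected(self):
        with pytest.raises(ValueError):
            classify_hairpin(PrecursorCandidate(None, "ACGU" * 10, 35, 22))

    def test_mature_in_loop_fails(self):
        # hairpin whose loop contains the 'mature': stem of 20, loop 22
        rng = random.Random(3)
        stem5 = "".join(rng.choice("GC") for _ in range(20))
        loop = "".join(rng.choice("ACGT") for _ in range(22))
        seq = (stem5 + loop + reverse_complement(stem5)).replace("T", "U")
        cand = PrecursorCandidate(None, seq, 20, 22).fold()
        call = classify_hairpin(cand)
        assert not call.passed


def test_major_terminal_loops_prunes_small_branches():
    # two stems, one with only 3 pairs: counts as one major loop
    db = "((((....))))..(((......)))"
    assert len(major_terminal_loops(db, prune=5)) == 0  # both minor
    db2 = "((((((((....))))))))..(((...)))"
    assert len(major_terminal_loops(db2, prune=5)) == 1


class TestNaming:
    def _cand(self, contig, start, seq="ACGUACGUACGUACGUACGUGCGC"):
        return PrecursorCandidate(GenomeLocus(contig, start, start + 22),
                                  seq, 0, 22)

    def test_both_arms_share_number(self):
        pre = self._cand("c1", 100)
        out = name_novel([(pre, "5p"), (pre, "3p")])
        assert sorted(n.name for n in out) == \
            ["ast-Novel-1-3p", "ast-Novel-1-5p"]

    def test_single_arm(self):
        out = name_novel([(self._cand("c1", 100), "3p")])
        assert out[0].name == "ast-Novel-1-3p"

    def test_numbering_by_coordinate_and_determinism(self):
        a = self._cand("c1", 500, "A" * 10 + "CGUACGUACGUA" + "A" * 10)
        b = self._cand("c1", 100, "G" * 10 + "CGUACGUACGUA" + "C" * 10)
        out1 = name_novel([(a, "5p"), (b, "3p")])
        out2 = name_novel([(b, "3p"), (a, "5p")])
        assert [n.name for n in out1] == [n.name for n in out2]
        by_name = {n.name: n.precursor.locus.start for n in out1}
        assert by_name["ast-Novel-1-3p"] == 100
        assert by_name["ast-Novel-2-5p"] == 500


class TestCheckNotKnown:
    def setup_method(self):
        self.known = SequenceCatalog("known_mirna",
                                     {"m": "TGTGATGTGACGTAGTGGTAC"})

    def test_identical_is_known_like(self):
        assert check_not_known("TGTGATGTGACGTAGTGGTAC", self.known) == "known-like"

    def test_distant_is_novel(self):
        assert check_not_known("CCCCAAAATTTTGGGGCCAAA", self.known) == "novel"

    def test_edit_distance_exactly_three(self):
        mutated = "AGTGATGTGACGTAGTGGACC"  # 3 edits from the known mature
        assert check_not_known(mutated, self.known) == "known-like"
        assert check_not_known(mutated, self.known, max_distance=2) == "novel"


def test_planted_recovery_and_shuffled_specificity(rng):
    """Planted hairpin loci are accepted; shuffled (structure-free) loci
    are rejected in at least 95% of 200 seeded trials."""
    from stagemir import synthetic_data as syn
    seeds = random.Random(99)
    recovered = total = 0
    for seed in (3, 4, 5):
        cfg = syn.SimulationConfig(seed=seed, n_known_mirnas=4, n_novel_loci=4,
                                   contig_length=8000, n_pirna_species=10)
        genome, _loci, truth = syn.simulate_genome(cfg)
        for _name, loc, arm, _mat in truth.novel_loci:
            total += 1
            cand = extract_precursor(genome, loc).fold()
            call = classify_hairpin(cand)
            if call.passed and call.arm == arm:
                recovered += 1
    assert recovered == total == 12

    rejected = 0
    n_trials = 200
    for t in range(n_trials):
        shuffled = "".join(seeds.sample("ACGT" * 43, 172))
        cand = PrecursorCandidate(None, shuffled.replace("T", "U"), 75, 22).fold()
        if not classify_hairpin(cand).passed:
            rejected += 1
    assert rejected / n_trials >= 0.95
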