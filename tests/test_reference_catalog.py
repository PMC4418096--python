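"""Hierarchical zero-mismatch read assignment and feature counting."""

import random

import pytest

from stagemir.io_small_rna import CollapsedRead
from stagemir.reference_catalog import (AssignmentResult, CountTable,
                                        SequenceCatalog, UNASSIGNED,
                                        assign_hierarchical, class_totals,
                                        count_features, dedupe_mature,
                                        locate_in_genome, match_known_mirna,
                                        reverse_complement)

MIR989 = "TGTGATGTGACGTAGTGGTAC"  # ast-miR-989 mature


@pytest.fixture
def known():
    return SequenceCatalog("known_mirna", {
        "ast-miR-989": MIR989,
        "ast-miR-263a": "AATGGCACTGGAAGAATTCACG",
    })


class TestMatchKnown:
    def test_exact_mature(self, known):
        assert match_known_mirna(MIR989, known) == "ast-miR-989"

    def test_internal_mismatch_rejected(self, known):
        seq = MIR989[:10] + ("A" if MIR989[10] != "A" else "C") + MIR989[11:]
        assert match_known_mirna(seq, known) is None

    def test_prefix_substring_matches(self, known):
        assert match_known_mirna(MIR989[:19], known) == "ast-miR-989"

    def test_isomir_flank_tolerance(self, known):
        assert match_known_mirna("AG" + MIR989 + "T", known) == "ast-miR-989"
        assert match_known_mirna("AGCC" + MIR989, known) is None  # 4 extras
        assert match_known_mirna("AG" + MIR989, known, flank_tolerance=0) is None


class TestDedupe:
    def test_duplicate_sequences_merge(self):
        cat = SequenceCatalog("known_mirna", {
            "dme-miR-1": "TGGAATGTAAAGAAGTATGGAG",
            "aga-miR-1": "TGGAATGTAAAGAAGTATGGAG",
        })
        out = dedupe_mature(cat)
        assert list(out.entries) == ["aga-miR-1"]  # lexicographic precedence

    def test_unique_catalog_unchanged(self, known):
        assert dedupe_mature(known).entries == known.entries

    def test_empty(self):
        assert len(dedupe_mature(SequenceCatalog("known_mirna", {}))) == 0


class TestHierarchy:
    def _catalogs(self):
        known = SequenceCatalog("known_mirna", {"m1": MIR989})
        genome = SequenceCatalog("genome", {
            "c1": "TTTT" + MIR989 + "GGGGCCCCAAAACCCCGGGGTTTT"})
        return known, genome

    def test_priority_known_over_genome(self):
        known, genome = self._catalogs()
        res = assign_hierarchical([CollapsedRead(MIR989, 1)], [known, genome])
        assert res[0].assigned_class == "known_mirna"

    def test_genome_only_read(self):
        known, genome = self._catalogs()
        r = CollapsedRead("GGGGCCCCAAAACCCCGGGG", 1)
        res = assign_hierarchical([r], [known, genome])
        assert res[0].assigned_class == "genome"

    def test_genome_matches_minus_strand(self):
        known, genome = self._catalogs()
        r = CollapsedRead(reverse_complement("GGGGCCCCAAAACCCCGGGG"), 1)
        res = assign_hierarchical([r], [known, genome])
        assert res[0].assigned_class == "genome"

    def test_unmatched_is_unassigned(self):
        known, genome = self._catalogs()
        res = assign_hierarchical([CollapsedRead("ATATATATATATATATAT", 1)],
                                  [known, genome])
        assert res[0].assigned_class == UNASSIGNED
        assert res[0].feature_name is None

    def test_catalog_order_enforced(self):
        known, genome = self._catalogs()
        with pytest.raises(ValueError):
            assign_hierarchical([], [genome, known])

    def test_order_stability(self, rng):
        known, genome = self._catalogs()
        reads = [CollapsedRead(MIR989, 2),
                 CollapsedRead("GGGGCCCCAAAACCCCGGGG", 1),
                 CollapsedRead("ATATATATATATATATAT", 5)]
        base = {r.sequence: a.assigned_class
                for r, a in zip(reads, assign_hierarchical(reads, [known, genome]))}
        for _ in range(5):
            rng.shuffle(reads)
            got = {r.sequence: a.assigned_class
                   for r, a in zip(reads, assign_hierarchical(reads, [known, genome]))}
            assert got == base


def test_brute_force_oracle_equivalence(rng):
    """Hash/substring assignment equals an all-pairs scan on small inputs."""
    def rand_seq(n):
        return "".join(rng.choice("ACGT") for _ in range(n))

    known = SequenceCatalog("known_mirna",
                            {f"k{i}": rand_seq(rng.randint(20, 23))
                             for i in range(15)})
    ncrna = SequenceCatalog("ncrna",
                            {f"n{i}": rand_seq(80) for i in range(10)})
    genome = SequenceCatalog("genome", {"c1": rand_seq(800), "c2": rand_seq(800)})
    reads = []
    for _ in range(60):
        mode = rng.random()
        if mode < 0.3:
            src = rng.choice(list(known.entries.values()))
            reads.append(CollapsedRead(src, 1))
        elif mode < 0.5:
            src = rng.choice(list(ncrna.entries.values()))
            i = rng.randint(0, len(src) - 20)
            reads.append(CollapsedRead(src[i:i + 20], 1))
        elif mode < 0.7:
            src = rng.choice(list(genome.entries.values()))
            i = rng.randint(0, len(src) - 22)
            s = src[i:i + 22]
            reads.append(CollapsedRead(
                s if rng.random() < 0.5 else reverse_complement(s), 1))
        else:
            reads.append(CollapsedRead(rand_seq(21), 1))
    got = assign_hierarchical(reads, [known, ncrna, genome])

    def oracle(seq):
        for name in sorted(known.entries):
            mat = known.entries[name]
            if seq == mat or seq in mat or \
                    (0 < len(seq) - len(mat) <= 3 and mat in seq):
                return "known_mirna"
        for name in sorted(ncrna.entries):
            if seq in ncrna.entries[name]:
                return "ncrna"
        for name in sorted(genome.entries):
            if seq in genome.entries[name] or \
                    seq in reverse_complement(genome.entries[name]):
                return "genome"
        return UNASSIGNED

    for r, a in zip(reads, got):
        assert a.assigned_class == oracle(r.sequence), r.sequence


class TestCounting:
    def test_counts_sum_collapsed(self):
        reads = [CollapsedRead(MIR989, 3), CollapsedRead(MIR989[:20], 2)]
        asg = [AssignmentResult(r.sequence, "known_mirna", "ast-miR-989")
               for r in reads]
        table = count_features(asg, reads, "AM")
        assert table.get("ast-miR-989", "AM") == 5
        assert table.library_totals["AM"] == 5

    def test_absent_feature_is_zero(self):
        table = count_features([], [], "AM")
        assert table.get("ast-miR-989", "AM") == 0

    def test_partition_property(self, small_simulation):
        """Each read lands in exactly one class; class sums + unassigned
        equal the library total."""
        from stagemir import pipeline
        cfg, genome, loci, truth, libs = small_simulation
        known = SequenceCatalog("known_mirna", dict(truth.known_matures))
        table, totals, assignments = pipeline.run_profile(
            libs, [known, genome], adapter=cfg.adapter)
        for stage, (reads, asg) in assignments.items():
            lib_total = sum(r.count for r in reads)
            assert sum(totals[stage].values()) == lib_total

    def test_tsv_round_trip(self, tmp_path):
        t = CountTable()
        t.set("ast-miR-989", "AM", 5)
        t.set("ast-miR-989", "AF", 4329)
        t.library_totals = {"AM": 1000, "AF": 2000}
        p = tmp_path / "counts.tsv"
        t.to_tsv(p)
        back = CountTable.from_tsv(p)
        assert back.get("ast-miR-989", "AF") == 4329
        assert back.library_totals == t.library_totals


def test_locate_in_genome():
    genome = SequenceCatalog("genome", {"c1": "AAAACCCCGGGGTTTTACGTACGTCCCC"})
    assert locate_in_genome("CCCCGGGGTTTTACGTACGT", genome) == ("c1", 4, 24, "+")
    rc = reverse_complement("CCCCGGGGTTTTACGTACGT")
    contig, start, end, strand = locate_in_genome(rc, genome)
    assert (contig, start, end, strand) == ("c1", 4, 24, "-")
    assert locate_in_genome("TTTTTTTTTTTTTTTTTTTT", genome) is None
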