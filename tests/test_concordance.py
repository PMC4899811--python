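"""Novelty classification, concordance grouping, consensus and read matching."""

import itertools

import pytest

from conftest import random_dna
from gme.concordance import (
    ConcordantGroup,
    ContigRecord,
    ExonAnnotation,
    KnownIndex,
    classify_contigs,
    classify_novel,
    concordant_groups,
    consensus_sequence,
    extract_cdna,
    match_reads,
    parse_velvet_id,
    read_depth,
)
from gme.motif_families import reverse_complement
from gme.repeat_finder import TandemRepeatHit
from gme.synthetic_data import SimulationConfig, simulate_genome


def contig(sample, node, seq, status="novel"):
    return ContigRecord(
        sample_id=sample,
        node_id=node,
        length=len(seq),
        kmer_coverage=1.0,
        sequence=seq,
        status=status,
    )


class TestParseVelvetId:
    def test_paper_example(self):
        assert parse_velvet_id("NODE_35_length_226_cov_17.079645") == (35, 226, 17.079645)

    def test_integer_coverage(self):
        assert parse_velvet_id("NODE_1_length_100_cov_0.0") == (1, 100, 0.0)

    @pytest.mark.parametrize(
        "bad,field",
        [
            ("NODE_x_length_10_cov_1", "node"),
            ("NODE_1_length_ten_cov_1", "length"),
            ("NODE_1_length_10_cov_abc", "cov"),
        ],
    )
    def test_malformed_field_named(self, bad, field):
        with pytest.raises(ValueError, match=field):
            parse_velvet_id(bad)

    def test_wrong_shape(self):
        with pytest.raises(ValueError):
            parse_velvet_id("CONTIG_1_length_10_cov_1")

    def test_roundtrip_through_record(self):
        c = contig("S1", 35, "A" * 226)
        assert parse_velvet_id(c.velvet_id)[:2] == (35, 226)


class TestReadDepth:
    def test_worked_example(self):
        # independent arithmetic: 17.079645 * 150 / (150 - 71 + 1)
        assert read_depth(17.079645, 150, 71) == pytest.approx(17.079645 * 150 / 80)
        assert read_depth(17.079645, 150, 71) == pytest.approx(32.0243, abs=1e-4)

    def test_k1_identity(self):
        for ck in (0.0, 1.5, 10.0):
            assert read_depth(ck, 100, 1) == pytest.approx(ck)

    def test_simple_ratio(self):
        assert read_depth(10, 100, 51) == pytest.approx(20.0)

    def test_linear_in_ck(self):
        assert read_depth(6, 150, 71) == pytest.approx(3 * read_depth(2, 150, 71))

    def test_validation(self):
        with pytest.raises(ValueError):
            read_depth(1.0, 50, 71)
        with pytest.raises(ValueError):
            read_depth(1.0, 50, 0)


@pytest.fixture(scope="module")
def ref():
    import numpy as np

    return random_dna(np.random.default_rng(5), 1200)


class TestClassifyNovel:
    def test_verbatim_substring_known(self, ref):
        assert classify_novel(contig("S", 1, ref[100:300]), [[ref]]) == "known"

    def test_reverse_complement_known(self, ref):
        assert classify_novel(contig("S", 1, reverse_complement(ref[100:300])), [[ref]]) == "known"

    def test_half_length_boundary(self, ref, rng):
        other = random_dna(rng, 200)
        just_under = other[:120] + ref[500:580]  # best match 80 <= 100
        just_over = other[:99] + ref[500:601]  # 101 > 100
        assert classify_novel(contig("S", 1, just_under), [[ref]]) == "novel"
        assert classify_novel(contig("S", 2, just_over), [[ref]]) == "known"

    def test_no_match_novel(self, ref, rng):
        assert classify_novel(contig("S", 1, random_dna(rng, 150)), [[ref]]) == "novel"

    def test_match_cannot_span_references(self, ref):
        # a contig straddling two separate reference sequences is not known
        a, b = ref[:200], ref[200:400]
        straddle = a[-60:] + b[:60]
        assert classify_novel(contig("S", 1, straddle), [[a], [b]]) == "novel"

    def test_empty_reference_warns_all_novel(self, ref):
        contigs = [contig("S", 1, ref[:100], status="unclassified")]
        with pytest.warns(UserWarning):
            classify_contigs(contigs, [])
        assert contigs[0].status == "novel"

    def test_monotone_in_references(self, ref, rng):
        c = contig("S", 1, ref[10:200])
        assert classify_novel(c, [[ref]]) == "known"
        assert classify_novel(c, [[ref], [random_dna(rng, 300)]]) == "known"


class TestAddFlanks:
    def make(self, rng):
        seq = random_dna(rng, 300)
        c = contig("S", 1, seq)
        return seq, c

    def hit(self, start, end):
        return TandemRepeatHit("c", start, end, 5, "AATGG", "AATGG", 4.0, 30, 100.0)

    def test_interior(self, rng):
        from gme.concordance import add_flanks

        seq, c = self.make(rng)
        assert add_flanks(self.hit(50, 70), c) == seq[20:100]

    def test_left_clamped(self, rng):
        from gme.concordance import add_flanks

        seq, c = self.make(rng)
        assert add_flanks(self.hit(5, 25), c) == seq[0:55]

    def test_zero_flank(self, rng):
        from gme.concordance import add_flanks

        seq, c = self.make(rng)
        assert add_flanks(self.hit(50, 70), c, flank=0) == seq[50:70]

    def test_out_of_range_rejected(self, rng):
        from gme.concordance import add_flanks

        _, c = self.make(rng)
        with pytest.raises(ValueError):
            add_flanks(self.hit(290, 310), c)


class TestConcordantGroups:
    def test_identical_across_samples(self, rng):
        seq = random_dna(rng, 300)
        groups = concordant_groups([contig("S1", 1, seq), contig("S2", 1, seq)], 0)
        assert len(groups) == 1
        assert groups[0].sample_count == 2
        assert groups[0].consensus == seq

    def test_one_mismatch_needs_tolerance(self, rng):
        seq = random_dna(rng, 300)
        other = "T" if seq[150] != "T" else "G"
        variant = seq[:150] + other + seq[151:]
        pair = [contig("S1", 1, seq), contig("S2", 1, variant)]
        assert concordant_groups(pair, 0) == []
        assert len(concordant_groups(pair, 1)) == 1

    def test_single_sample_never_groups(self, rng):
        seq = random_dna(rng, 300)
        assert concordant_groups([contig("S1", 1, seq), contig("S1", 2, seq)], 1) == []

    def test_reverse_complement_members_group(self, rng):
        seq = random_dna(rng, 300)
        groups = concordant_groups(
            [contig("S1", 1, seq), contig("S2", 1, reverse_complement(seq))], 0
        )
        assert len(groups) == 1

    def test_seventy_percent_rule_uses_shorter_query(self, rng):
        long_seq = random_dna(rng, 400)
        short = long_seq[100:250]  # 150 bases, fully contained: >70% of short
        groups = concordant_groups([contig("S1", 1, long_seq), contig("S2", 1, short)], 0)
        assert len(groups) == 1

    def test_insufficient_overlap_no_edge(self, rng):
        a = random_dna(rng, 200)
        b = a[:100] + random_dna(rng, 100)  # only 100 of 200 shared (<= 140)
        assert concordant_groups([contig("S1", 1, a), contig("S2", 1, b)], 1) == []

    def test_partition_and_order_invariance(self, rng):
        seqs = [random_dna(rng, 250) for _ in range(3)]
        contigs = []
        node = itertools.count(1)
        for sample in ("S1", "S2", "S3"):
            for seq in seqs:
                contigs.append(contig(sample, next(node), seq))
        expected = None
        for perm in (contigs, contigs[::-1], sorted(contigs, key=lambda c: c.sequence)):
            groups = concordant_groups(list(perm), 1)
            sig = sorted(
                tuple(sorted(m.contig_id for m in g.members)) for g in groups
            )
            if expected is None:
                expected = sig
            assert sig == expected
        assert len(expected) == 3
        # every qualifying contig appears in exactly one group
        all_members = [m for g in groups for m in g.members]
        assert len(all_members) == len(set(m.contig_id for m in all_members)) == 9

    def test_zero_mismatch_refines_one_mismatch(self, rng):
        seq = random_dna(rng, 300)
        other = "T" if seq[10] != "T" else "G"
        variant = seq[:10] + other + seq[11:]
        contigs = [
            contig("S1", 1, seq),
            contig("S2", 1, seq),
            contig("S3", 1, variant),
        ]
        g0 = concordant_groups(contigs, 0)
        g1 = concordant_groups(contigs, 1)
        members0 = [frozenset(m.contig_id for m in g.members) for g in g0]
        members1 = [frozenset(m.contig_id for m in g.members) for g in g1]
        for group in members0:
            assert any(group <= big for big in members1)

    def test_known_contigs_excluded(self, rng):
        seq = random_dna(rng, 300)
        pair = [contig("S1", 1, seq, status="known"), contig("S2", 1, seq)]
        assert concordant_groups(pair, 1) == []

    def test_mismatch_mode_validated(self):
        with pytest.raises(ValueError):
            concordant_groups([], 2)


class TestConsensus:
    def test_majority_vote(self, rng):
        seq = random_dna(rng, 300)
        other = "T" if seq[42] != "T" else "G"
        variant = seq[:42] + other + seq[43:]
        group = concordant_groups(
            [contig("S1", 1, seq), contig("S2", 1, variant), contig("S3", 1, seq)], 1
        )[0]
        assert group.consensus == seq

    def test_two_way_tie_goes_to_anchor(self, rng):
        seq = random_dna(rng, 300)
        longer = seq + random_dna(rng, 5)  # anchor (longest)
        other = "T" if seq[42] != "T" else "G"
        variant = seq[:42] + other + seq[43:]
        group = concordant_groups([contig("S1", 1, longer), contig("S2", 1, variant)], 1)[0]
        assert group.consensus == longer

    def test_overhang_extends_consensus(self, rng):
        core = random_dna(rng, 260)
        left = random_dna(rng, 30) + core
        right = core + random_dna(rng, 25)
        group = concordant_groups([contig("S1", 1, left), contig("S2", 1, right)], 0)[0]
        assert group.consensus == left + right[-25:]

    def test_irreconcilable_member_flagged(self, rng):
        group = ConcordantGroup(
            group_id="g",
            members=[contig("S1", 1, random_dna(rng, 200)), contig("S2", 1, random_dna(rng, 150))],
            mismatch_mode=1,
        )
        consensus = consensus_sequence(group)
        assert consensus == group.members[0].sequence
        assert group.unplaced_members == ["S2:NODE_1"]


class TestExtractCdna:
    def test_concatenation(self, rng):
        seq = random_dna(rng, 100)
        c = contig("S", 1, seq)
        ann = ExonAnnotation("c", [(0, 30), (60, 90)])
        assert extract_cdna(c, ann) == seq[:30] + seq[60:90]

    def test_single_exon_rejected(self, rng):
        c = contig("S", 1, random_dna(rng, 100))
        with pytest.raises(ValueError):
            extract_cdna(c, ExonAnnotation("c", [(0, 30)]))

    def test_tiling_exons_give_contig(self, rng):
        seq = random_dna(rng, 90)
        c = contig("S", 1, seq)
        assert extract_cdna(c, ExonAnnotation("c", [(0, 45), (45, 90)])) == seq

    @pytest.mark.parametrize("exons", [[(0, 30), (20, 50)], [(0, 30), (60, 120)], [(30, 30), (40, 50)]])
    def test_bad_exons_rejected(self, exons, rng):
        c = contig("S", 1, random_dna(rng, 100))
        with pytest.raises(ValueError):
            extract_cdna(c, ExonAnnotation("c", exons))


class TestMatchReads:
    def test_exact_substring_counts(self, rng):
        q = random_dna(rng, 300)
        table = match_reads({"q": q}, {"s1": [("r1", q[50:125])]})
        assert table.loc["q", "s1"] == 1

    def test_partial_match_below_threshold(self, rng):
        q = random_dna(rng, 300)
        read = q[50:100] + random_dna(rng, 25)  # 50 contiguous <= 0.7*75
        table = match_reads({"q": q}, {"s1": [("r1", read)]})
        assert table.loc["q", "s1"] == 0

    def test_additive_across_sets(self, rng):
        q = random_dna(rng, 300)
        read = ("r", q[10:85])
        table = match_reads({"q": q}, {"a": [read], "b": [read], "c": [read]})
        assert list(table.loc["q", ["a", "b", "c"]]) == [1, 1, 1]
        assert table.loc["q", "total"] == 3

    def test_reverse_complement_read_counts(self, rng):
        q = random_dna(rng, 300)
        table = match_reads({"q": q}, {"s": [("r", reverse_complement(q[50:125]))]})
        assert table.loc["q", "s"] == 1

    def test_short_query_against_longer_read(self, rng):
        q = random_dna(rng, 60)
        read = random_dna(rng, 10) + q + random_dna(rng, 5)
        table = match_reads({"q": q}, {"s": [("r", read)]})
        assert table.loc["q", "s"] == 1


def test_end_to_end_classification_on_synthetic(small_config):
    """Contigs cut from the reference are known; extra segments are novel."""
    reference, extra, _ = simulate_genome(small_config)
    index = KnownIndex([[reference]])
    for start in range(0, 2000, 400):
        piece = contig("S", 1, reference[start : start + 300], status="unclassified")
        assert classify_novel(piece, index) == "known"
    for seq in extra.values():
        assert classify_novel(contig("S", 1, seq, status="unclassified"), index) == "novel"
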