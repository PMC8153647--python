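import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circat import catalog
from circat.align import SplitAlignment, revcomp
from circat.catalog import (
    CircCandidate,
    aggregate,
    classify,
    detect_shs,
    flank_complementarity,
    nesting,
    splice_signal,
    structural_category,
)
from circat.reference import Gene, GeneAnnotation, Genome, Transcript


def aln(read_id, A=1000, D=3000, chrom="chr1", strand="+"):
    return SplitAlignment(read_id, chrom, strand, A, D, 50, (50, 50), 0)


class TestAggregate:
    def test_counts_per_sample(self):
        cands = aggregate({"s1": [aln("r1"), aln("r2"), aln("r3")]}, min_support=2)
        assert len(cands) == 1 and cands[0].counts == {"s1": 3}

    def test_below_threshold_dropped(self):
        assert aggregate({"s1": [aln("r1")], "s2": [aln("r2")]}, min_support=2) == []

    def test_multi_sample_vector(self):
        cands = aggregate(
            {"s1": [aln("a"), aln("b")], "s2": [aln(f"c{i}") for i in range(5)]},
            min_support=2,
        )
        assert cands[0].counts == {"s1": 2, "s2": 5}

    def test_duplicate_read_ids_counted_once(self):
        cands = aggregate({"s1": [aln("r1"), aln("r1"), aln("r2")]}, min_support=2)
        assert cands[0].counts == {"s1": 2}

    def test_id_is_deterministic(self):
        c = aggregate({"s1": [aln("a"), aln("b")]}, min_support=2)[0]
        assert c.circ_id == "chr1_1000_3000_+"


@pytest.fixture(scope="module")
def flat_ann():
    genome = Genome({"chr1": "A" * 10_000})
    t = Transcript("t1", "g1", "chr1", "+", [(1000, 1400), (2000, 2400), (3000, 3400)])
    return GeneAnnotation([Gene("g1", "chr1", "+", [t])], genome)


class TestClassify:
    def test_both_points_at_boundaries(self, flat_ann):
        assert classify(CircCandidate("chr1", "+", 2000, 2400), flat_ann) == "canonical"

    def test_interior_circle(self, flat_ann):
        assert classify(CircCandidate("chr1", "+", 2050, 2350), flat_ann) == "complete_icirc"

    def test_one_boundary_point(self, flat_ann):
        assert classify(CircCandidate("chr1", "+", 2000, 2500), flat_ann) == "partial_icirc"

    def test_boundary_tolerance(self, flat_ann):
        c = CircCandidate("chr1", "+", 2002, 2398)
        assert classify(c, flat_ann) == "complete_icirc"
        assert classify(c, flat_ann, boundary_tolerance=2) == "canonical"

    def test_planted_truth_classes(self, toy_truth):
        for t in toy_truth.circles:
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            assert classify(c, toy_truth.annotation) == t.class_label


class TestStructuralCategory:
    @pytest.mark.parametrize(
        "A,D,expected,kept",
        [
            (2000, 2400, "single_exon", True),        # full exon
            (2050, 2350, "single_exon", True),        # inside exon
            (1450, 1900, "single_intron", True),      # inside intron
            (2000, 2600, "adjacent_exon_intron", True),  # exon2 + part of intron2
            (1200, 2600, "other", False),             # exon1..intron2 span
            (1000, 3400, "other", False),             # whole gene
            (5000, 6000, "intergenic", True),
        ],
    )
    def test_categories(self, flat_ann, A, D, expected, kept):
        structure, keep = structural_category(CircCandidate("chr1", "+", A, D), flat_ann)
        assert (structure, keep) == (expected, kept)

    def test_intron_then_exon_order_accepted(self, flat_ann):
        structure, keep = structural_category(CircCandidate("chr1", "+", 1600, 2200), flat_ann)
        assert (structure, keep) == ("adjacent_exon_intron", True)

    def test_planted_truth_structures(self, toy_truth):
        for t in toy_truth.circles:
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            structure, keep = structural_category(c, toy_truth.annotation)
            assert (structure, keep) == (t.structure, True)


class TestSpliceSignal:
    def test_planted_signals_match_truth(self, toy_truth):
        for t in toy_truth.circles:
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            assert splice_signal(c, toy_truth.genome) == t.signal, t.circ_id

    def test_signal_found_after_homology_shift(self):
        """GT-AG present only 2 nt downstream of the canonical junction is
        still a splice signal: the junction is ambiguous over its homology
        window.  Verified against a brute-force window scan."""
        rng = np.random.default_rng(0)
        seq = list("".join(rng.choice(list("AC"), size=400)))
        A, D = 100, 300
        # 2 nt of forward homology ("AG" at both junction starts), GT just
        # beyond the donor-side homology: the signal exists only at shift 2
        seq[A : A + 2] = "AG"
        seq[D : D + 2] = "AG"
        seq[D + 2 : D + 4] = "GT"
        seq[A + 2] = "T"  # break homology at exactly 2 (donor side has G)
        g = Genome({"chr1": "".join(seq)})
        cand = CircCandidate("chr1", "+", A, D)
        # brute-force oracle over the shift window
        f, _ = detect_shs(g, "chr1", A, D)
        found = any(
            g.chromosomes["chr1"][D + i : D + i + 2] == "GT"
            and g.chromosomes["chr1"][A + i - 2 : A + i] == "AG"
            for i in range(f + 1)
        )
        assert splice_signal(cand, g) == found
        assert found  # the planted shifted signal is real

    def test_minus_strand_uses_reverse_complement_signal(self):
        seq = list("C" * 400)
        A, D = 100, 300
        seq[A - 2 : A] = "AC"
        seq[D : D + 2] = "CT"
        seq[A] = "G"  # break forward homology (seq[D] stays C)
        g = Genome({"chr1": "".join(seq)})
        assert splice_signal(CircCandidate("chr1", "-", A, D), g)
        assert not splice_signal(CircCandidate("chr1", "+", A, D), g)


def shs_oracle(g: str, A: int, D: int, max_len: int = 60):
    """Brute-force string-comparison SHS oracle."""
    f = max(
        (h for h in range(0, max_len + 1)
         if h <= D - A and D + h <= len(g) and g[A : A + h] == g[D : D + h]),
        default=0,
    )
    b = max(
        (h for h in range(0, max_len + 1)
         if h <= D - A and A - h >= 0 and g[A - h : A] == g[D - h : D]),
        default=0,
    )
    return f + b, g[A - b : A + f]


class TestDetectSHS:
    def test_no_shared_sequence(self):
        g = Genome({"chr1": "ACGT" * 100})
        # ACGT-periodic: positions 100 and 301 differ in phase
        length, _ = detect_shs(g, "chr1", 100, 301)
        assert length == 0

    def test_planted_forward_homology(self):
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("ACGT"), size=500)))
        A, D = 100, 300
        seq[A : A + 3] = "ACG"
        seq[D : D + 3] = "ACG"
        seq[A + 3], seq[D + 3] = "A", "C"
        seq[A - 1], seq[D - 1] = "A", "C"
        g = "".join(seq)
        assert detect_shs(Genome({"chr1": g}), "chr1", A, D) == shs_oracle(g, A, D)
        assert detect_shs(Genome({"chr1": g}), "chr1", A, D)[0] == 3

    def test_backward_plus_forward(self):
        rng = np.random.default_rng(2)
        seq = list("".join(rng.choice(list("ACGT"), size=500)))
        A, D = 100, 300
        seq[A - 2 : A + 1] = "GCA"   # b=2 and f=1 arms
        seq[D - 2 : D + 1] = "GCA"
        seq[A + 1], seq[D + 1] = "A", "C"
        seq[A - 3], seq[D - 3] = "A", "C"
        g = "".join(seq)
        length, s = detect_shs(Genome({"chr1": g}), "chr1", A, D)
        assert (length, s) == (3, g[A - 2 : A + 1])
        assert (length, s) == shs_oracle(g, A, D)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_oracle_on_random_junctions(self, seed):
        rng = np.random.default_rng(seed)
        g = "".join(rng.choice(list("ACGT"), size=2000))
        A = int(rng.integers(60, 900))
        D = int(rng.integers(A + 70, 1900))
        assert detect_shs(Genome({"chr1": g}), "chr1", A, D) == shs_oracle(g, A, D)

    def test_planted_truth_shs(self, toy_truth):
        for t in toy_truth.circles:
            length, _ = detect_shs(toy_truth.genome, t.chrom, t.acceptor, t.donor)
            assert length == t.shs_length, t.circ_id


def flank_oracle(up: str, down: str, min_match: int):
    """All-pairs longest exact reverse-complement substring match."""
    rcd = revcomp(down)
    best = 0
    for i in range(len(up)):
        for j in range(len(rcd)):
            k = 0
            while i + k < len(up) and j + k < len(rcd) and up[i + k] == rcd[j + k]:
                k += 1
            best = max(best, k)
    return best if best >= min_match else 0


class TestFlankComplementarity:
    def test_planted_inverted_repeat_found(self, toy_truth):
        for t in toy_truth.circles:
            if not t.flank_repeat:
                continue
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            fp = flank_complementarity(c, toy_truth.genome)
            assert fp is not None and fp.length >= t.flank_repeat

    def test_agrees_with_all_pairs_oracle(self, toy_truth):
        g = toy_truth.genome
        for t in toy_truth.circles[:10]:
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            up = g.fetch(t.chrom, t.acceptor - 200, t.acceptor)
            down = g.fetch(t.chrom, t.donor, t.donor + 200)
            expected = flank_oracle(up, down, 8)
            fp = flank_complementarity(c, g)
            assert (fp.length if fp else 0) == expected

    def test_degenerate_threshold_always_matches(self, toy_truth):
        t = toy_truth.circles[0]
        c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
        assert flank_complementarity(c, toy_truth.genome, min_match=1) is not None

    def test_reported_coordinates_are_reverse_complementary(self, toy_truth):
        g = toy_truth.genome
        for t in toy_truth.circles:
            if not t.flank_repeat:
                continue
            c = CircCandidate(t.chrom, t.strand, t.acceptor, t.donor)
            fp = flank_complementarity(c, g)
            up = g.fetch(t.chrom, fp.upstream_start, fp.upstream_start + fp.length)
            down = g.fetch(t.chrom, fp.downstream_start, fp.downstream_start + fp.length)
            assert up == revcomp(down) == fp.sequence


class TestNesting:
    def cand(self, A, D, strand="+", hosts=()):
        c = CircCandidate("chr1", strand, A, D)
        c.host_genes = list(hosts)
        return c

    def test_proper_containment_reported(self):
        outer, inner = self.cand(100, 1000), self.cand(200, 900)
        pairs, _ = nesting([outer, inner])
        assert pairs == [(outer.circ_id, inner.circ_id)]

    def test_disjoint_and_identical_not_reported(self):
        a, b = self.cand(100, 1000), self.cand(2000, 3000)
        assert nesting([a, b])[0] == []
        assert nesting([self.cand(100, 1000), self.cand(100, 1000)])[0] == []

    def test_strand_mismatch_not_contained(self):
        pairs, _ = nesting([self.cand(100, 1000), self.cand(200, 900, strand="-")])
        assert pairs == []

    def test_multi_circle_host_genes(self):
        a = self.cand(100, 1000, hosts=["g1"])
        b = self.cand(2000, 3000, hosts=["g1"])
        c = self.cand(4000, 5000, hosts=["g2"])
        _, multi = nesting([a, b, c])
        assert set(multi) == {"g1"}


def test_class_partition_on_toy_catalog(toy_truth, toy_alignments):
    """Every aggregated candidate receives exactly one class label and the
    label distribution matches the planted design."""
    cands = aggregate({"S1": toy_alignments}, min_support=2)
    catalog.annotate_catalog(cands, toy_truth.genome, toy_truth.annotation)
    assert all(c.class_label in catalog.CLASSES for c in cands)
    from collections import Counter

    got = Counter(c.class_label for c in cands)
    want = Counter(t.class_label for t in toy_truth.circles)
    assert got == want


def test_catalog_tsv_round_trip(tmp_path, toy_truth, toy_alignments):
    cands = aggregate({"S1": toy_alignments}, min_support=2)
    catalog.annotate_catalog(cands, toy_truth.genome, toy_truth.annotation)
    path = tmp_path / "cat.tsv"
    catalog.write_catalog_tsv(cands, path, header_note="test")
    back = catalog.read_catalog_tsv(path)
    assert [(c.circ_id, c.class_label, c.structure, c.counts) for c in back] == [
        (c.circ_id, c.class_label, c.structure, c.counts) for c in cands
    ]
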