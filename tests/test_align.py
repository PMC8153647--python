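import numpy as np
import pytest

from circat import align, simulate
from circat.align import (
    AnchorHit,
    DetectionParams,
    GenomeIndex,
    canonicalize,
    detect_pairs,
    extract_anchors,
    find_reversed_anchor_pairs,
    map_linear,
    revcomp,
)
from circat.reference import Genome

PARAMS = DetectionParams()


def junction_read(genome, chrom, A, D, s, L=100):
    """Sense-strand read crossing the junction of circle [A, D) split at s."""
    g = genome.chromosomes[chrom]
    return g[D - s : D] + g[A : A + L - s]


class TestExtractAnchors:
    def test_standard_geometry(self):
        read = "A" * 60 + "C" * 40
        left, right = extract_anchors(read, 20)
        assert (left, right) == (read[:20], read[80:])

    def test_abutting_anchors(self):
        read = "ACGT" * 10  # L = 2x
        left, right = extract_anchors(read, 20)
        assert left + right == read

    def test_short_read_skipped(self):
        assert extract_anchors("A" * 39, 20) is None


class TestMapLinear:
    def test_exact_substring_maps(self, toy_truth, toy_index):
        g = toy_truth.genome
        read = g.fetch("chr1", 5000, 5100)
        p = map_linear(read, g, toy_index, PARAMS)
        assert p is not None and (p.chrom, p.start, p.mismatches) == ("chr1", 5000, 0)

    def test_reverse_complement_maps(self, toy_truth, toy_index):
        g = toy_truth.genome
        p = map_linear(revcomp(g.fetch("chr1", 5000, 5100)), g, toy_index, PARAMS)
        assert p is not None and p.orient == "-" and p.start == 5000

    def test_three_mismatches_rejected(self, toy_truth, toy_index):
        g = toy_truth.genome
        read = list(g.fetch("chr1", 5000, 5100))
        for i in (10, 50, 90):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        assert map_linear("".join(read), g, toy_index, PARAMS) is None

    def test_junction_read_is_unmappable(self, toy_truth, toy_index):
        """A back-fusion read has no contiguous placement: its prefix and
        suffix come from discontiguous loci."""
        c = toy_truth.circles[0]
        read = junction_read(toy_truth.genome, c.chrom, c.acceptor, c.donor, 50)
        assert map_linear(read, toy_truth.genome, toy_index, PARAMS) is None

    def test_n_rich_read_skipped(self, toy_truth, toy_index):
        read = "N" * 30 + toy_truth.genome.fetch("chr1", 0, 70)
        assert map_linear(read, toy_truth.genome, toy_index, PARAMS) is None


class TestReversedAnchorPairs:
    def hit(self, chrom, start, uniq=40):
        return AnchorHit(chrom, start, 0, uniq)

    def test_reversed_orientation_pairs(self):
        pairs = find_reversed_anchor_pairs(
            [self.hit("chr1", 5000)], [self.hit("chr1", 1000)], PARAMS, 100
        )
        assert len(pairs) == 1

    def test_forward_splice_geometry_excluded(self):
        assert not find_reversed_anchor_pairs(
            [self.hit("chr1", 1000)], [self.hit("chr1", 5000)], PARAMS, 100
        )

    def test_cross_chromosome_excluded(self):
        assert not find_reversed_anchor_pairs(
            [self.hit("chr1", 5000)], [self.hit("chr2", 1000)], PARAMS, 100
        )

    def test_low_mapq_anchor_excluded(self):
        assert not find_reversed_anchor_pairs(
            [self.hit("chr1", 5000, uniq=0)], [self.hit("chr1", 1000)], PARAMS, 100
        )

    def test_span_limit(self):
        p = DetectionParams(max_span=1000)
        assert not find_reversed_anchor_pairs(
            [self.hit("chr1", 5000)], [self.hit("chr1", 1000)], p, 100
        )


class TestResolveSplit:
    def test_error_free_junction_recovers_planted_coordinates(self, toy_truth, toy_index):
        for c in toy_truth.circles[:5]:
            read = junction_read(toy_truth.genome, c.chrom, c.acceptor, c.donor, 47)
            res = align._split_align_oriented(read, toy_truth.genome, toy_index, PARAMS)
            assert res is not None
            chrom, A, D, s, window, mm = res
            assert (chrom, A, D, mm) == (c.chrom, c.acceptor, c.donor, 0)

    def test_shift_window_width_is_shs_plus_one(self, toy_truth, toy_index):
        """A junction with h nt of flank homology has h+1 equally valid splits."""
        for c in toy_truth.circles:
            if c.shs_length == 0:
                continue
            read = junction_read(toy_truth.genome, c.chrom, c.acceptor, c.donor, 50)
            res = align._split_align_oriented(read, toy_truth.genome, toy_index, PARAMS)
            chrom, A, D, s, window, mm = res
            assert window[1] - window[0] + 1 == c.shs_length + 1
            assert (A, D) == (c.acceptor, c.donor)

    def test_three_errors_rejected(self, toy_truth, toy_index):
        c = toy_truth.circles[0]
        # errors placed away from the junction so no split shift can absorb them
        read = list(junction_read(toy_truth.genome, c.chrom, c.acceptor, c.donor, 50))
        for i in (5, 30, 95):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        res = align._split_align_oriented("".join(read), toy_truth.genome, toy_index, PARAMS)
        assert res is None


class TestCanonicalize:
    def test_single_and_leftmost(self):
        assert canonicalize([45]) == (45, (45, 45))
        assert canonicalize([46, 45, 47]) == (45, (45, 47))

    def test_non_contiguous_keeps_smallest(self, caplog):
        s, _ = canonicalize([40, 42])
        assert s == 40

    def test_reads_with_different_splits_share_canonical_coordinates(
        self, toy_truth, toy_index
    ):
        c = next(x for x in toy_truth.circles if x.shs_length >= 2)
        results = set()
        for s in (40, 41, 60):
            read = junction_read(toy_truth.genome, c.chrom, c.acceptor, c.donor, s)
            res = align._split_align_oriented(read, toy_truth.genome, toy_index, PARAMS)
            results.add((res[0], res[1], res[2]))
        assert results == {(c.chrom, c.acceptor, c.donor)}


class TestMatePairConstraint:
    def test_interior_mate_accepted_outside_rejected(self, toy_truth, toy_index):
        c = toy_truth.circles[0]
        g = toy_truth.genome
        inside = revcomp(g.fetch(c.chrom, c.acceptor + 5, c.acceptor + 105))
        outside = revcomp(g.fetch(c.chrom, c.donor + 2000, c.donor + 2100))
        ok = align.mate_within_circle(
            inside, g, toy_index, c.chrom, c.acceptor, c.donor, "-", PARAMS
        )
        bad = align.mate_within_circle(
            outside, g, toy_index, c.chrom, c.acceptor, c.donor, "-", PARAMS
        )
        assert ok == "interior" and bad is None

    def test_rotated_mate_recovers_short_circle(self, toy_truth, toy_index):
        """Both mates of a fragment longer than the circle cross the junction;
        the rotated-circle rule still recovers the planted coordinates."""
        c = toy_truth.circles[11]
        pairs = simulate.simulate_rotated_pairs(toy_truth, c.circ_id, 4, seed=3)
        alns, _ = detect_pairs(pairs, toy_truth.genome, index=toy_index)
        assert len(alns) == 4
        assert {(a.acceptor, a.donor, a.mate_flag) for a in alns} == {
            (c.acceptor, c.donor, "rotated")
        }

    def test_strict_mode_rejects_rotated(self, toy_truth, toy_index):
        c = toy_truth.circles[11]
        pairs = simulate.simulate_rotated_pairs(toy_truth, c.circ_id, 4, seed=3)
        strict = DetectionParams(mate_mode="strict")
        alns, _ = detect_pairs(pairs, toy_truth.genome, params=strict, index=toy_index)
        assert alns == []


def test_soundness_on_linear_only_reads(toy_truth, toy_index):
    """Reads simulated purely from linear transcripts yield zero junctions."""
    reads = simulate.simulate_reads(
        toy_truth, seed=11, n_linear_pairs=3000,
        samples=("LIN",),
    )
    pairs = [p for p in reads["LIN"][0] if p[0].startswith("lin|")]
    alns, _ = detect_pairs(pairs, toy_truth.genome, index=toy_index)
    assert alns == []


def test_strand_symmetry_under_genome_mirroring(toy_truth, toy_index):
    """Detecting the same read pairs against the reverse-complemented genome
    yields the mirrored junction on the opposite strand."""
    c = toy_truth.circles[0]
    reads = simulate.simulate_reads(toy_truth, seed=13, n_linear_pairs=0)
    pairs = [p for p in reads["S1"][0] if p[0].startswith(c.circ_id + "|")]
    mirrored = Genome(
        {chrom: revcomp(seq) for chrom, seq in toy_truth.genome.chromosomes.items()}
    )
    alns, _ = detect_pairs(pairs, mirrored)
    n = toy_truth.genome.lengths[c.chrom]
    assert alns, "junction lost under mirroring"
    assert {(a.chrom, a.strand, a.acceptor, a.donor) for a in alns} == {
        (c.chrom, "-" if c.strand == "+" else "+", n - c.donor, n - c.acceptor)
    }


def test_uniqueness_pseudo_mapq_scale(toy_truth, toy_index):
    """A uniquely placed anchor scores 40; a repeated anchor scores 0."""
    g = toy_truth.genome
    anchor = g.fetch("chr1", 4000, 4020)
    hits = align.anchor_hits(anchor, g, toy_index, PARAMS)
    assert [h.uniqueness for h in hits] == [40]
    rep = Genome({"chr1": g.fetch("chr1", 0, 5000) + g.fetch("chr1", 3000, 5000)})
    idx = GenomeIndex(rep)
    hits = align.anchor_hits(anchor, rep, idx, PARAMS)
    assert len(hits) == 2 and all(h.uniqueness == 0 for h in hits)
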