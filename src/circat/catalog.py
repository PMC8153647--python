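"""circRNA candidate catalog: aggregation, classification, junction features.

Split alignments are aggregated per unique back-fusion point (chrom, strand,
A, D) across samples.  Against the annotation each candidate is classified:

* canonical       — both BF points at annotated intron-exon boundaries
* partial_icirc   — exactly one BF point at a boundary
* complete_icirc  — neither point at a boundary (includes intergenic circles)

and restricted to the unambiguous structural categories (single exon, single
intron, adjacent exon+intron pair, intergenic); anything wider is labelled
"other" and excluded from the abundant set.  Junction features computed from
the genome: GT-AG splice-signal presence (evaluated over the homology shift
window, since detection itself uses no splice signal), short homologous
sequence (SHS) length at the junction flanks, reverse-complementary flank
pairing, and nesting/multi-circRNA host genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .align import SplitAlignment, revcomp
from .reference import GeneAnnotation, Genome

log = logging.getLogger(__name__)

__all__ = [
    "CircCandidate",
    "FlankPairing",
    "aggregate",
    "classify",
    "structural_category",
    "splice_signal",
    "detect_shs",
    "flank_complementarity",
    "nesting",
    "annotate_catalog",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_catalog_bed",
]

CLASSES = ("canonical", "partial_icirc", "complete_icirc")
STRUCTURES = ("single_exon", "single_intron", "adjacent_exon_intron", "intergenic", "other")


@dataclass(frozen=True)
class FlankPairing:
    length: int
    upstream_start: int    # genomic start of the match in the upstream flank
    downstream_start: int  # genomic start of the reverse-complement match downstream
    sequence: str


@dataclass
class CircCandidate:
    chrom: str
    strand: str
    acceptor: int
    donor: int
    counts: dict[str, int] = field(default_factory=dict)  # sample -> supporting pairs
    shift_width: int = 1
    class_label: str | None = None
    structure: str | None = None
    keep: bool = True
    has_splice_signal: bool | None = None
    shs_length: int = 0
    shs_sequence: str = ""
    flank_pairing: FlankPairing | None = None
    host_genes: list[str] = field(default_factory=list)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}_{self.acceptor}_{self.donor}_{self.strand}"

    @property
    def max_support(self) -> int:
        return max(self.counts.values(), default=0)


def aggregate(
    alignments_by_sample: dict[str, list[SplitAlignment]], min_support: int = 2
) -> list[CircCandidate]:
    """One candidate per unique (chrom, strand, A, D) with per-sample counts.

    Counts are numbers of distinct supporting read pairs.  Candidates whose
    support is below `min_support` in every sample are dropped.
    """
    table: dict[tuple, CircCandidate] = {}
    for sample, alns in alignments_by_sample.items():
        seen: set[tuple] = set()
        for a in alns:
            dedup = (sample, a.read_id, a.chrom, a.strand, a.acceptor, a.donor)
            if dedup in seen:
                continue
            seen.add(dedup)
            key = (a.chrom, a.strand, a.acceptor, a.donor)
            cand = table.get(key)
            if cand is None:
                cand = CircCandidate(a.chrom, a.strand, a.acceptor, a.donor)
                table[key] = cand
            cand.counts[sample] = cand.counts.get(sample, 0) + 1
            cand.shift_width = max(cand.shift_width, a.shift_window[1] - a.shift_window[0] + 1)
    out = [c for c in table.values() if c.max_support >= min_support]
    out.sort(key=lambda c: (c.chrom, c.acceptor, c.donor, c.strand))
    return out


def classify(
    cand: CircCandidate,
    annotation: GeneAnnotation,
    boundary_tolerance: int = 0,
    strand_aware: bool = True,
) -> str:
    """Class label from the distances of A and D to annotated exon boundaries."""
    at = (
        annotation.boundary_distance(cand.chrom, cand.strand, cand.acceptor, strand_aware)
        <= boundary_tolerance
    )
    dt = (
        annotation.boundary_distance(cand.chrom, cand.strand, cand.donor, strand_aware)
        <= boundary_tolerance
    )
    if at and dt:
        return "canonical"
    if at or dt:
        return "partial_icirc"
    return "complete_icirc"


def structural_category(
    cand: CircCandidate, annotation: GeneAnnotation, strand_aware: bool = True
) -> tuple[str, bool]:
    """Structure label and keep/drop decision.

    Kept categories: [A, D) within a single exon, a single intron, a pair of
    adjacent exon+intron (either order), or wholly intergenic.  Wider spans
    are labelled "other" and excluded from the abundant set — inferring the
    internal structure of a multi-feature circle from junction reads alone
    is unreliable.
    """
    A, D = cand.acceptor, cand.donor
    for (s, e) in annotation.intergenic_intervals(cand.chrom):
        if s <= A and D <= e:
            return "intergenic", True
    single = None
    adjacent = False
    for t in annotation.transcripts:
        if t.chrom != cand.chrom:
            continue
        if strand_aware and t.strand != cand.strand:
            continue
        introns = t.introns
        for (s, e) in t.exons:
            if s <= A and D <= e:
                single = "single_exon"
        for (s, e) in introns:
            if s <= A and D <= e:
                single = single or "single_intron"
        # adjacent exon+intron pairs, in either order along the genome
        feats = sorted([(s, e, "exon") for s, e in t.exons] + [(s, e, "intron") for s, e in introns])
        for (f1, f2) in zip(feats, feats[1:]):
            if f1[2] == f2[2] or f1[1] != f2[0]:
                continue
            if f1[0] <= A and D <= f2[1] and A < f1[1] and D > f2[0]:
                adjacent = True
    if single:
        return single, True
    if adjacent:
        return "adjacent_exon_intron", True
    return "other", False


def detect_shs(
    genome: Genome, chrom: str, acceptor: int, donor: int, max_len: int = 60
) -> tuple[int, str]:
    """Short homologous sequence at the two junction flanks.

    Forward arm f: largest h with genome[A:A+h] == genome[D:D+h]; backward
    arm b likewise upstream.  Reported length is f + b and the sequence
    spans genome[A-b : A+f].  Arms are capped at `max_len` and at the circle
    span so the two windows cannot cross each other.
    """
    g = genome.chromosomes[chrom]
    n = len(g)
    span = donor - acceptor
    f = 0
    while (
        f < max_len
        and f < span
        and donor + f < n
        and g[acceptor + f] == g[donor + f]
    ):
        f += 1
    b = 0
    while (
        b < max_len
        and b < span
        and acceptor - b - 1 >= 0
        and g[acceptor - b - 1] == g[donor - b - 1]
    ):
        b += 1
    return f + b, g[acceptor - b : acceptor + f]


def splice_signal(cand: CircCandidate, genome: Genome, max_shift: int = 60) -> bool:
    """GT-AG check, strand-adjusted, over the junction's homology shift window.

    Detection reports the leftmost equivalent (A, D); homology of length f
    at the flanks makes (A+i, D+i) for i in [0, f] the same junction, and
    the splice signal is an attribute of the junction, not of one shift.
    On '+' the donor dinucleotide just 3' of D must be GT and the acceptor
    dinucleotide just 5' of A must be AG; on '-' the reverse complement
    geometry applies (AC before A, CT after D).
    """
    g = genome.chromosomes[cand.chrom]
    n = len(g)
    A, D = cand.acceptor, cand.donor
    f = 0
    while f < max_shift and D + f < n and f < D - A and g[A + f] == g[D + f]:
        f += 1
    for i in range(0, f + 1):
        a, d = A + i, D + i
        if a - 2 < 0 or d + 2 > n:
            log.debug("junction %s within 2 nt of chromosome end", cand.circ_id)
            continue
        if cand.strand == "+":
            if g[d : d + 2] == "GT" and g[a - 2 : a] == "AG":
                return True
        else:
            if g[a - 2 : a] == "AC" and g[d : d + 2] == "CT":
                return True
    return False


def flank_complementarity(
    cand: CircCandidate,
    genome: Genome,
    flank_window: int = 200,
    min_match: int = 8,
) -> FlankPairing | None:
    """Longest exact reverse-complement match between the two BF flanks.

    Searches the upstream flank [A-flank_window, A) against the downstream
    flank [D, D+flank_window); truncated at chromosome ends.  Reported only
    when the match length reaches `min_match`.
    """
    g = genome.chromosomes[cand.chrom]
    n = len(g)
    up_s = max(0, cand.acceptor - flank_window)
    up = g[up_s : cand.acceptor]
    down_e = min(n, cand.donor + flank_window)
    down = g[cand.donor : down_e]
    if not up or not down:
        return None
    rcd = revcomp(down)
    # longest common substring via rolling DP
    best_len, best_i, best_j = 0, -1, -1
    prev = [0] * (len(rcd) + 1)
    for i in range(1, len(up) + 1):
        cur = [0] * (len(rcd) + 1)
        ci = up[i - 1]
        for j in range(1, len(rcd) + 1):
            if ci == rcd[j - 1]:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best_len:
                    best_len, best_i, best_j = v, i, j
        prev = cur
    if best_len < min_match:
        return None
    up_start = up_s + best_i - best_len
    # rcd index j-1 runs 3'->5' of down: convert match back to down coordinates
    down_start = cand.donor + len(down) - best_j
    seq = up[best_i - best_len : best_i]
    return FlankPairing(best_len, up_start, down_start, seq)


def nesting(cands: list[CircCandidate]) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Proper containments (outer, inner) on the same strand, and host genes
    producing at least two candidates."""
    pairs = []
    for outer in cands:
        for inner in cands:
            if outer is inner or outer.chrom != inner.chrom or outer.strand != inner.strand:
                continue
            if (
                outer.acceptor <= inner.acceptor
                and inner.donor <= outer.donor
                and (outer.acceptor, outer.donor) != (inner.acceptor, inner.donor)
            ):
                pairs.append((outer.circ_id, inner.circ_id))
    hosts: dict[str, list[str]] = {}
    for c in cands:
        for gid in c.host_genes:
            hosts.setdefault(gid, []).append(c.circ_id)
    multi = {gid: ids for gid, ids in hosts.items() if len(ids) >= 2}
    return pairs, multi


def annotate_catalog(
    cands: list[CircCandidate],
    genome: Genome,
    annotation: GeneAnnotation,
    boundary_tolerance: int = 0,
    strand_aware: bool = True,
    shs_max_len: int = 60,
    flank_window: int = 200,
    flank_min_match: int = 8,
) -> list[CircCandidate]:
    """Fill class, structure, features and host genes for every candidate."""
    for c in cands:
        c.class_label = classify(c, annotation, boundary_tolerance, strand_aware)
        c.structure, c.keep = structural_category(c, annotation, strand_aware)
        c.has_splice_signal = splice_signal(c, genome, max_shift=shs_max_len)
        c.shs_length, c.shs_sequence = detect_shs(
            genome, c.chrom, c.acceptor, c.donor, max_len=shs_max_len
        )
        c.flank_pairing = flank_complementarity(c, genome, flank_window, flank_min_match)
        c.host_genes = sorted(
            g.gene_id
            for g in annotation.genes
            if g.chrom == c.chrom
            and g.span[0] <= c.acceptor
            and c.donor <= g.span[1]
        )
    return cands


# ---------------------------------------------------------------------------
# catalog I/O (plain TSV / BED6+, diffable)

_TSV_COLS = [
    "circ_id", "chrom", "acceptor", "donor", "strand", "class", "structure",
    "keep", "splice_signal", "shs_length", "shs_sequence", "shift_width",
    "flank_pairing_length", "host_genes", "counts",
]


def write_catalog_tsv(cands: list[CircCandidate], path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("\t".join(_TSV_COLS) + "\n")
        for c in cands:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.circ_id, c.chrom, c.acceptor, c.donor, c.strand,
                        c.class_label or ".", c.structure or ".",
                        int(c.keep), int(bool(c.has_splice_signal)),
                        c.shs_length, c.shs_sequence or ".", c.shift_width,
                        c.flank_pairing.length if c.flank_pairing else 0,
                        ",".join(c.host_genes) or ".",
                        json.dumps(c.counts, sort_keys=True),
                    )
                )
                + "\n"
            )


def read_catalog_tsv(path) -> list[CircCandidate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        c = CircCandidate(
            chrom=str(r["chrom"]),
            strand=str(r["strand"]),
            acceptor=int(r["acceptor"]),
            donor=int(r["donor"]),
            counts={k: int(v) for k, v in json.loads(r["counts"]).items()},
            shift_width=int(r["shift_width"]),
            class_label=None if r["class"] == "." else str(r["class"]),
            structure=None if r["structure"] == "." else str(r["structure"]),
            keep=bool(int(r["keep"])),
            has_splice_signal=bool(int(r["splice_signal"])),
            shs_length=int(r["shs_length"]),
            shs_sequence="" if r["shs_sequence"] == "." else str(r["shs_sequence"]),
        )
        hg = str(r["host_genes"])
        c.host_genes = [] if hg == "." else hg.split(",")
        out.append(c)
    return out


def write_catalog_bed(cands: list[CircCandidate], path) -> None:
    """BED6+4: chrom, A, D, id, max support, strand, class, structure, signal, shs."""
    with open(path, "w") as fh:
        for c in cands:
            fh.write(
                f"{c.chrom}\t{c.acceptor}\t{c.donor}\t{c.circ_id}\t{c.max_support}\t"
                f"{c.strand}\t{c.class_label}\t{c.structure}\t"
                f"{int(bool(c.has_splice_signal))}\t{c.shs_length}\n"
            )
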