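"""Seeded synthetic data: genomes, annotations, planted circRNAs, reads,
expression and ceRNA matrices.

The generator emulates the structure of a stranded, paired-end 100 bp
ribo-depleted RNA-seq experiment: linear background fragments from spliced
transcripts, plus circles whose junction-spanning read has its mate inside
the circle (or, for circles shorter than the fragment, crossing the
junction itself).  Planted circles carry the designed class/structure,
short homologous sequence (SHS) at the junction flanks, GT-AG presence or
absence, and optional inverted flank repeats; truth coordinates are always
stored in canonical (leftmost-shift) form so detector output can be
compared exactly.  Every generator is deterministic under (seed, params).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .reference import Gene, GeneAnnotation, Genome, Transcript

__all__ = [
    "CircDesign",
    "PlantedCircle",
    "TruthSet",
    "make_genome",
    "default_design",
    "plant_circles",
    "simulate_reads",
    "simulate_rotated_pairs",
    "simulate_expression",
    "simulate_cerna",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_KIND_LABELS = {
    "canonical": ("canonical", "single_exon"),
    "exon_icirc": ("complete_icirc", "single_exon"),
    "intron_icirc": ("complete_icirc", "single_intron"),
    "partial": ("partial_icirc", "adjacent_exon_intron"),
    "intergenic": ("complete_icirc", "intergenic"),
}


@dataclass
class CircDesign:
    kind: str                    # one of _KIND_LABELS
    shs_length: int = 0
    signal: bool | None = None   # None = whatever the locus provides naturally
    flank_repeat: int = 0

    def __post_init__(self):
        if self.kind not in _KIND_LABELS:
            raise ValueError(f"unknown circle kind {self.kind!r}")
        if self.signal and self.shs_length:
            raise ValueError("a planted splice signal requires shs_length == 0")
        if self.shs_length > 12:
            raise ValueError("planted SHS capped at 12 nt to keep anchors unique")


@dataclass
class PlantedCircle:
    circ_id: str
    chrom: str
    strand: str
    acceptor: int
    donor: int
    class_label: str
    structure: str
    shs_length: int
    signal: bool
    flank_repeat: int
    depths: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.donor - self.acceptor


@dataclass
class TruthSet:
    genome: Genome
    annotation: GeneAnnotation
    circles: list[PlantedCircle]
    seed: int

    def to_tsv(self, path) -> None:
        rows = []
        for c in self.circles:
            rows.append(
                {
                    "circ_id": c.circ_id, "chrom": c.chrom, "acceptor": c.acceptor,
                    "donor": c.donor, "strand": c.strand, "class": c.class_label,
                    "structure": c.structure, "shs_length": c.shs_length,
                    "signal": int(c.signal), "flank_repeat": c.flank_repeat,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome + annotation


def make_genome(
    seed: int,
    n_chromosomes: int = 2,
    chrom_length: int = 50_000,
    gene_density: float = 1.2,
) -> tuple[Genome, GeneAnnotation]:
    """Random i.i.d. A/C/G/T chromosomes with multi-exon GT-AG gene models.

    `gene_density` is genes per 10 kb.  Genes are laid out left to right
    with intergenic gaps, 3–6 exons of 200–450 nt and introns of 300–700 nt
    whose terminal dinucleotides are set to the canonical splice signal
    (strand-adjusted).  Every chromosome keeps at least one annotation-free
    region.
    """
    if chrom_length < 10_000:
        raise ValueError("chromosomes must be at least 10 kb")
    rng = np.random.default_rng(seed)
    chroms: dict[str, bytearray] = {}
    genes: list[Gene] = []
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = bytearray(rng.choice(_BASES, size=chrom_length).tobytes())
        n_genes = int(round(gene_density * chrom_length / 10_000))
        pos = int(rng.integers(900, 1600))
        gi = 0
        while gi < n_genes:
            n_ex = int(rng.integers(3, 7))
            ex_lens = rng.integers(200, 451, size=n_ex)
            in_lens = rng.integers(300, 701, size=n_ex - 1)
            span = int(ex_lens.sum() + in_lens.sum())
            if pos + span + 900 > chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cur = pos
            for k in range(n_ex):
                exons.append((cur, cur + int(ex_lens[k])))
                cur += int(ex_lens[k])
                if k < n_ex - 1:
                    istart, iend = cur, cur + int(in_lens[k])
                    if strand == "+":
                        seq[istart : istart + 2] = b"GT"
                        seq[iend - 2 : iend] = b"AG"
                    else:
                        seq[istart : istart + 2] = b"CT"
                        seq[iend - 2 : iend] = b"AC"
                    cur = iend
            gid = f"{chrom}_g{gi + 1}"
            t = Transcript(f"{gid}_t1", gid, chrom, strand, exons)
            genes.append(Gene(gid, chrom, strand, [t]))
            pos = cur + int(rng.integers(900, 2000))
            gi += 1
        chroms[chrom] = seq
        if n_genes > 0 and gi == 0:
            raise ValueError("gene parameters made genes unplaceable")
    genome = Genome({c: s.decode("ascii") for c, s in chroms.items()})
    ann = GeneAnnotation(genes, genome)
    return genome, ann


def default_design() -> list[CircDesign]:
    """The 30-circle study design used throughout the synthetic suite:
    10 canonical, 10 complete interior (5 exon + 5 intron), 5 partial,
    5 intergenic; SHS lengths peaked at 2 nt with a tail, two circles with
    12 nt inverted flank repeats."""
    design = [CircDesign("canonical", signal=True) for _ in range(10)]
    design += [
        CircDesign("exon_icirc", shs_length=0, signal=False, flank_repeat=12),
        CircDesign("exon_icirc", shs_length=2, signal=False),
        CircDesign("exon_icirc", shs_length=3, signal=False),
        CircDesign("exon_icirc", shs_length=5, signal=False),
        CircDesign("exon_icirc", shs_length=0, signal=True),
        CircDesign("intron_icirc", shs_length=0, signal=False, flank_repeat=12),
        CircDesign("intron_icirc", shs_length=2, signal=False),
        CircDesign("intron_icirc", shs_length=2, signal=False),
        CircDesign("intron_icirc", shs_length=4, signal=False),
        CircDesign("intron_icirc", shs_length=12, signal=False),
        CircDesign("partial", signal=True),
        CircDesign("partial", signal=True),
        CircDesign("partial", signal=True),
        CircDesign("partial", shs_length=2, signal=False),
        CircDesign("partial", shs_length=2, signal=False),
        CircDesign("intergenic", shs_length=0, signal=False),
        CircDesign("intergenic", shs_length=0, signal=False),
        CircDesign("intergenic", shs_length=2, signal=False),
        CircDesign("intergenic", shs_length=3, signal=False),
        CircDesign("intergenic", shs_length=6, signal=False),
    ]
    return design


# SHS homology content avoids G and T so neither GT (donor) nor AG
# (acceptor) can arise inside the homology tract on the plus strand; the
# minus-strand signals (AC/CT) are excluded the same way by avoiding G/T.
_SHS_PATTERN = "CACACACACACA"


def _pick_base(rng, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def plant_circles(
    genome: Genome,
    annotation: GeneAnnotation,
    design: list[CircDesign],
    seed: int,
    samples: tuple[str, ...] = ("S1",),
    depth_range: tuple[int, int] = (5, 12),
) -> TruthSet:
    """Edit the genome to realise the designed circles; return genome+truth.

    Junction flanks are edited so that (i) the planted coordinates are the
    canonical leftmost shift (no backward homology), (ii) forward homology
    is exactly the designed SHS length, and (iii) GT-AG presence matches
    the design at every shift of the homology window.
    """
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}

    # allocate loci: one feature (exon / intron / exon+intron / gap) per circle
    used: dict[str, set] = {}
    gene_feats = []
    for g in annotation.genes:
        t = g.transcripts[0]
        gene_feats.append((g, t))
    gaps = [
        (chrom, s, e)
        for chrom in genome.chromosomes
        for (s, e) in annotation.intergenic_intervals(chrom)
        if e - s >= 900
    ]
    gap_cursor = 0

    circles: list[PlantedCircle] = []
    for di, d in enumerate(design):
        cls, structure = _KIND_LABELS[d.kind]
        placed = None
        if d.kind == "intergenic":
            if gap_cursor >= len(gaps):
                raise ValueError("no intergenic gap available for design entry")
            chrom, gs, ge = gaps[gap_cursor]
            gap_cursor += 1
            A = gs + 200
            D = A + 300 + int(rng.integers(0, 200))
            if D > ge - 200:
                D = ge - 200
            strand = "+" if rng.random() < 0.5 else "-"
            placed = (chrom, strand, A, D)
        else:
            for g, t in gene_feats:
                u = used.setdefault(g.gene_id, set())
                exons, introns = t.exons, t.introns
                if d.kind == "canonical":
                    for i in range(1, len(exons) - 1):
                        if ("e", i) in u:
                            continue
                        A, D = exons[i]
                        u.add(("e", i))
                        placed = (g.chrom, t.strand, A, D)
                        break
                elif d.kind == "exon_icirc":
                    for i in range(len(exons)):
                        if ("e", i) in u or exons[i][1] - exons[i][0] < 180:
                            continue
                        s0, e0 = exons[i]
                        A, D = s0 + 15, e0 - 15
                        u.add(("e", i))
                        placed = (g.chrom, t.strand, A, D)
                        break
                elif d.kind == "intron_icirc":
                    for i in range(len(introns)):
                        if ("i", i) in u:
                            continue
                        s0, e0 = introns[i]
                        A, D = s0 + 25, e0 - 25
                        u.add(("i", i))
                        placed = (g.chrom, t.strand, A, D)
                        break
                elif d.kind == "partial":
                    for i in range(1, len(exons) - 1):
                        if ("e", i) in u or ("i", i) in u:
                            continue
                        A = exons[i][0]
                        i_s, i_e = introns[i]
                        delta = min(200, i_e - i_s - 60)
                        D = i_s + delta
                        u.add(("e", i))
                        u.add(("i", i))
                        placed = (g.chrom, t.strand, A, D)
                        break
                if placed:
                    break
        if placed is None:
            raise ValueError(f"design entry {di} ({d.kind}) could not be placed")
        chrom, strand, A, D = placed
        g = seqs[chrom]
        h = d.shs_length
        signal = d.signal
        if signal is None:
            signal = d.kind == "canonical"

        if h > 0:
            pat = _SHS_PATTERN[:h].encode("ascii")
            g[A : A + h] = pat
            g[D : D + h] = pat
        if signal and d.kind != "canonical":
            if strand == "+":
                g[A - 2 : A] = b"AG"
                g[D : D + 2] = b"GT"
            else:
                g[A - 2 : A] = b"AC"
                g[D : D + 2] = b"CT"
        _fix_junction(g, A, D, strand, h, signal, d.kind == "canonical" or signal, rng)

        if d.flank_repeat:
            r = d.flank_repeat
            up = bytes(g[A - 40 - r : A - 40]).decode("ascii")
            g[D + 40 : D + 40 + r] = revcomp(up).encode("ascii")

        circ_id = f"circ{di + 1:03d}"
        depths = {
            s: int(rng.integers(depth_range[0], depth_range[1] + 1)) for s in samples
        }
        circles.append(
            PlantedCircle(
                circ_id, chrom, strand, A, D, cls, structure,
                h, bool(signal), d.flank_repeat, depths,
            )
        )

    edited = Genome({c: s.decode("ascii") for c, s in seqs.items()})
    truth = TruthSet(edited, annotation, circles, seed)
    _self_consistency(truth)
    return truth


def _fix_junction(
    g: bytearray,
    A: int,
    D: int,
    strand: str,
    h: int,
    want_signal: bool,
    protect_donor: bool,
    rng,
    max_attempts: int = 300,
) -> None:
    """Verify-and-repair loop enforcing the designed junction properties.

    After editing, the junction must have forward homology exactly h,
    backward homology 0 (so the planted coordinates are the canonical
    leftmost shift) and splice-signal presence equal to `want_signal`
    at every shift of the homology window.  Repairs are random single-base
    edits outside the homology tract; `protect_donor` keeps the signal
    dinucleotides (positions D..D+1 and A-2..A-1) untouched and shifts
    homology repairs to the acceptor side instead.
    """
    if strand == "+":
        acc, don = b"AG", b"GT"
    else:
        acc, don = b"AC", b"CT"

    def forward() -> int:
        f = 0
        while f < 60 and f < D - A and D + f < len(g) and g[A + f] == g[D + f]:
            f += 1
        return f

    def backward() -> int:
        b = 0
        while b < 60 and b < D - A and A - b - 1 >= 0 and g[A - b - 1] == g[D - b - 1]:
            b += 1
        return b

    def signal_at() -> int | None:
        """First homology shift carrying the strand-adjusted GT-AG, else None."""
        for i in range(0, forward() + 1):
            if bytes(g[A + i - 2 : A + i]) == acc and bytes(g[D + i : D + i + 2]) == don:
                return i
        return None

    for _ in range(max_attempts):
        f = forward()
        if f != h:
            # homology tract guarantees f >= h; trim the first mismatch point
            pos = A + h if protect_donor else D + h
            g[pos] = ord(_pick_base(rng, chr(g[pos])))
            continue
        if backward() > 0:
            g[D - 1] = ord(_pick_base(rng, chr(g[D - 1])))
            continue
        hit = signal_at()
        if want_signal and hit is None:
            g[A - 2 : A] = acc
            g[D : D + 2] = don
            continue
        if not want_signal and hit is not None:
            # break the donor dinucleotide of the offending shift, editing
            # only outside the homology tract (its G/T char is always there)
            i = hit
            pos = D + i if D + i >= D + h else D + i + 1
            g[pos] = ord(_pick_base(rng, chr(g[pos])))
            continue
        return
    raise AssertionError("junction repair did not converge")


def _self_consistency(truth: TruthSet) -> None:
    """Planted circles must pass the catalog module's own validators."""
    from . import catalog as cat

    for c in truth.circles:
        cand = cat.CircCandidate(c.chrom, c.strand, c.acceptor, c.donor)
        got_cls = cat.classify(cand, truth.annotation)
        got_struct, keep = cat.structural_category(cand, truth.annotation)
        shs_len, _ = cat.detect_shs(truth.genome, c.chrom, c.acceptor, c.donor)
        sig = cat.splice_signal(cand, truth.genome)
        if (got_cls, got_struct, keep, shs_len, sig) != (
            c.class_label, c.structure, True, c.shs_length, c.signal
        ):
            raise AssertionError(
                f"planted circle {c.circ_id} fails self-consistency: "
                f"got {(got_cls, got_struct, keep, shs_len, sig)}, "
                f"designed {(c.class_label, c.structure, True, c.shs_length, c.signal)}"
            )


# ---------------------------------------------------------------------------
# reads


def _circle_transcript(genome: Genome, c: PlantedCircle) -> str:
    seq = genome.fetch(c.chrom, c.acceptor, c.donor)
    return seq if c.strand == "+" else revcomp(seq)


def _spliced_transcript(genome: Genome, t: Transcript) -> str:
    seq = "".join(genome.fetch(t.chrom, s, e) for (s, e) in t.exons)
    return seq if t.strand == "+" else revcomp(seq)


def _mutate(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        cur = chr(arr[i])
        arr[i] = ord(_pick_base(rng, cur))
    return arr.tobytes().decode("ascii")


def simulate_reads(
    truth: TruthSet,
    seed: int,
    read_length: int = 100,
    error_rate: float = 0.0,
    n_linear_pairs: int = 2_000,
    samples: tuple[str, ...] | None = None,
):
    """Paired reads per sample: junction pairs for every planted circle at
    its designed depth, plus a linear background from spliced transcripts.

    Junction pairs sample the split position uniformly within the
    detectable range [25, L-25] and alternate which mate crosses the
    junction; the other mate lands wholly inside the circle.  Substitution
    errors are i.i.d.; qualities are constant.  Returns
    {sample: (pairs, provenance)} where pairs is a list of
    (read_id, seq1, seq2) and provenance a DataFrame of true origins.
    """
    rng = np.random.default_rng(seed)
    # a separate stream for sequencing errors keeps the fragment layout
    # identical across error rates
    err_rng = np.random.default_rng(seed + 10_007)
    L = read_length
    genome = truth.genome
    out = {}
    samples = samples or tuple(sorted({s for c in truth.circles for s in c.depths}))
    transcripts = [t for t in truth.annotation.transcripts
                   if sum(e - s for s, e in t.exons) >= L + 60]
    for sample in samples:
        pairs = []
        prov = []
        for c in truth.circles:
            T = _circle_transcript(genome, c)
            n = len(T)
            if n < L + 10:
                raise ValueError(f"circle {c.circ_id} shorter than read length + 10")
            depth = c.depths.get(sample, 0)
            for j in range(depth):
                s = int(rng.integers(25, L - 24))
                gmax = min(60, n - L)
                gap = int(rng.integers(5, max(6, gmax)))
                F = L + s + gap
                frag = (T + T)[n - s : n - s + F]
                junction_mate = 2 if j % 2 == 0 else 1
                if junction_mate == 2:
                    r2 = frag[:L]          # crosses the junction
                    r1 = revcomp(frag[F - L :])
                else:
                    # reposition so the junction falls in the last L bases
                    u = n - L - gap
                    frag = (T + T)[u : u + F]
                    r2 = frag[:L]
                    r1 = revcomp(frag[F - L :])
                rid = f"{c.circ_id}|{sample}|J{j}"
                pairs.append((rid, _mutate(r1, err_rng, error_rate), _mutate(r2, err_rng, error_rate)))
                prov.append({"read_id": rid, "origin": c.circ_id,
                             "kind": "junction", "junction_mate": junction_mate})
        if transcripts:
            lens = np.array([sum(e - s for s, e in t.exons) for t in transcripts], dtype=float)
            w = lens / lens.sum()
            for j in range(n_linear_pairs):
                t = transcripts[int(rng.choice(len(transcripts), p=w))]
                T = _spliced_transcript(genome, t)
                F = int(np.clip(rng.normal(250, 25), L + 10, len(T)))
                u = int(rng.integers(0, len(T) - F + 1))
                frag = T[u : u + F]
                r2 = frag[:L]
                r1 = revcomp(frag[-L:])
                rid = f"lin|{sample}|{j}"
                pairs.append((rid, _mutate(r1, err_rng, error_rate), _mutate(r2, err_rng, error_rate)))
                prov.append({"read_id": rid, "origin": t.transcript_id,
                             "kind": "linear", "junction_mate": 0})
        out[sample] = (pairs, pd.DataFrame(prov))
    return out


def simulate_rotated_pairs(
    truth: TruthSet, circle_id: str, n_pairs: int, seed: int, read_length: int = 100
):
    """Pairs in which BOTH mates cross the junction (circle < fragment)."""
    rng = np.random.default_rng(seed)
    L = read_length
    c = next(x for x in truth.circles if x.circ_id == circle_id)
    T = _circle_transcript(truth.genome, c)
    n = len(T)
    pairs = []
    for j in range(n_pairs):
        s = int(rng.integers(25, L - 24))
        g = int(rng.integers(25, L - 24))
        F = n + s + g
        frag = (T * 3)[n - s : n - s + F]
        r2 = frag[:L]
        r1 = revcomp(frag[F - L :])
        pairs.append((f"{c.circ_id}|rot|{j}", r1, r2))
    return pairs


def write_fastq(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, s1, s2 in pairs:
            f1.write(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def read_fastq_pairs(path1, path2):
    """Yield (read_id, seq1, seq2) from two mate FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path1) as f1, open(path2) as f2:
        for (t1, s1, _), (t2, s2, _) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = t1.split()[0]
            for suffix in ("/1", "/2"):
                if rid.endswith(suffix):
                    rid = rid[: -len(suffix)]
            yield rid, s1, s2


# ---------------------------------------------------------------------------
# expression / ceRNA matrices


def simulate_expression(
    n_circ: int,
    n_per_group: int,
    seed: int,
    fraction_de: float = 0.0,
    fold_change: float = 1.0,
    mean: float = 10.0,
    dispersion: float = 0.3,
    library_size: float = 2e7,
    groups: tuple[str, str] = ("PP", "NN"),
):
    """Negative-binomial count matrix with an optional planted fold change.

    Real junction counts are overdispersed, hence the NB model.  The first
    round(fraction_de * n_circ) rows are DE in group A, alternating up and
    down by `fold_change`.  Returns (ExpressionMatrix, truth DataFrame).
    """
    from .quantify import ExpressionMatrix

    rng = np.random.default_rng(seed)
    ga, gb = groups
    samples = [f"{ga}{i + 1:02d}" for i in range(n_per_group)] + [
        f"{gb}{i + 1:02d}" for i in range(n_per_group)
    ]
    labels = [ga] * n_per_group + [gb] * n_per_group
    r = 1.0 / dispersion
    n_de = int(round(fraction_de * n_circ))
    rows = []
    truth_rows = []
    for i in range(n_circ):
        mu_a = mu_b = mean
        direction = "none"
        if i < n_de:
            if i % 2 == 0:
                mu_a, direction = mean * fold_change, "up"
            else:
                mu_a, direction = mean / fold_change, "down"
        counts_a = rng.negative_binomial(r, r / (r + mu_a), size=n_per_group)
        counts_b = rng.negative_binomial(r, r / (r + mu_b), size=n_per_group)
        rows.append(np.concatenate([counts_a, counts_b]))
        truth_rows.append({"circ_id": f"c{i + 1:05d}", "is_de": i < n_de,
                           "direction": direction})
    counts = pd.DataFrame(
        np.vstack(rows), index=[r["circ_id"] for r in truth_rows], columns=samples
    )
    mapped = pd.Series(
        (library_size * np.exp(rng.normal(0, 0.1, size=len(samples)))).astype(np.int64),
        index=samples,
    )
    matrix = ExpressionMatrix(counts, mapped, pd.Series(labels, index=samples))
    return matrix, pd.DataFrame(truth_rows)


def simulate_cerna(
    n_samples: int = 30,
    seed: int = 0,
    correlation: float = 0.8,
    n_mirnas: int = 3,
    targets_per_mirna: int = 20,
    fraction_associated: float = 0.5,
    circ_id: str = "circ001",
):
    """Planted circRNA–miRNA–mRNA cascade for association testing.

    The circRNA binds all but the last miRNA.  A `fraction_associated`
    subset of each bound miRNA's targets co-varies with the circRNA
    (Spearman ~ `correlation`) and is DE in the concordant (down)
    direction; the rest are independent, half of them DE-concordant to
    provide false-association candidates.  Returns a dict with expression
    vectors, target-hit lists, the DE gene table, and the truth frame.
    """
    from .cerna import BindingSite, MiRNATargetHit

    if not (0.0 <= correlation <= 1.0):
        raise ValueError("correlation must be within [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    z = rng.normal(size=n_samples)
    circ_expr = pd.Series(np.exp(1.5 + 0.6 * z), index=samples, name=circ_id)

    circ_hits = []
    gene_hits = []
    truth_rows = []
    de_rows = []
    gene_expr_rows = {}
    noise_w = math.sqrt(max(0.0, 1.0 - correlation**2))
    gidx = 0
    for mi in range(n_mirnas):
        mirna = f"miR-{mi + 1}"
        bound = mi < n_mirnas - 1
        if bound:
            n_sites = int(rng.integers(1, 6))
            circ_hits.append(
                MiRNATargetHit(
                    mirna, circ_id, "circRNA",
                    [BindingSite(10 * k, 10 * k + 7, 150.0, -12.0) for k in range(n_sites)],
                )
            )
        n_assoc = int(round(fraction_associated * targets_per_mirna))
        for ti in range(targets_per_mirna):
            gidx += 1
            gene = f"gene{gidx:03d}"
            associated = bound and ti < n_assoc
            if associated:
                y = correlation * z + noise_w * rng.normal(size=n_samples)
                de_rows.append({"gene_id": gene, "is_de": True, "direction": "down"})
            else:
                y = rng.normal(size=n_samples)
                if ti % 2 == 0:
                    de_rows.append({"gene_id": gene, "is_de": True, "direction": "down"})
                else:
                    de_rows.append({"gene_id": gene, "is_de": False, "direction": "up"})
            gene_expr_rows[gene] = np.exp(1.2 + 0.5 * y)
            gene_hits.append(
                MiRNATargetHit(mirna, gene, "mRNA", [BindingSite(5, 12, 150.0, -10.0)])
            )
            truth_rows.append({"gene_id": gene, "mirna_id": mirna,
                               "circ_bound": bound, "associated": bool(associated)})
    gene_expr = pd.DataFrame(gene_expr_rows, index=samples).T
    return {
        "circ_id": circ_id,
        "circ_direction": "down",
        "circ_expression": circ_expr,
        "gene_expression": gene_expr,
        "circ_hits": circ_hits,
        "gene_hits": gene_hits,
        "de_genes": pd.DataFrame(de_rows),
        "truth": pd.DataFrame(truth_rows),
    }
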