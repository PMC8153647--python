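"""Reference genome and gene-annotation model.

All coordinates are 0-based half-open internally.  GTF input/output converts
at the boundary (GTF is 1-based inclusive).  The annotation derives, per
transcript, the intron set (gaps between consecutive exons) and, per
chromosome, the intergenic intervals (complement of gene spans, unstranded).
The set of exon boundary coordinates per (chromosome, strand) drives the
classification of back-fusion points into canonical / partial / complete
interior circRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
import gffutils

__all__ = [
    "Genome",
    "Transcript",
    "Gene",
    "GeneAnnotation",
    "load_genome",
    "load_annotation",
]

_VALID = set("ACGTN")


class Genome:
    """Chromosome name -> uppercase nucleotide sequence, with strict bounds."""

    def __init__(self, chromosomes: dict[str, str]):
        if not chromosomes:
            raise ValueError("genome contains no sequences")
        for name, seq in chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
        self.chromosomes = {name: seq.upper() for name, seq in chromosomes.items()}
        for name, seq in self.chromosomes.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"chromosome {name!r} contains non-ACGTN symbols: {sorted(bad)}")
        self.lengths = {name: len(seq) for name, seq in self.chromosomes.items()}
        self._arrays: dict[str, np.ndarray] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract [start, end); coordinates outside the chromosome are an error."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.lengths[chrom]
        if not (0 <= start <= end <= n):
            raise IndexError(f"fetch({chrom}, {start}, {end}) outside [0, {n}]")
        return self.chromosomes[chrom][start:end]

    def array(self, chrom: str) -> np.ndarray:
        """uint8 view of a chromosome (cached), for fast Hamming comparisons."""
        arr = self._arrays.get(chrom)
        if arr is None:
            arr = np.frombuffer(self.chromosomes[chrom].encode("ascii"), dtype=np.uint8)
            self._arrays[chrom] = arr
        return arr

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_genome(path) -> Genome:
    """Read a (possibly line-wrapped) FASTA into a :class:`Genome`."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, 0-based half-open

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s}, {e}) in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (may be empty for single-exon)."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        s = min(t.span[0] for t in self.transcripts)
        e = max(t.span[1] for t in self.transcripts)
        return (s, e)


class GeneAnnotation:
    """Exon/intron/intergenic interval model over a genome."""

    def __init__(self, genes: list[Gene], genome: Genome, validate: bool = True):
        self.genes = genes
        self.genome = genome
        self.chrom_lengths = dict(genome.lengths)
        for g in genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
            for t in g.transcripts:
                if t.span[1] > self.chrom_lengths[g.chrom]:
                    raise ValueError(
                        f"transcript {t.transcript_id} extends past end of {g.chrom}"
                    )
        self.transcripts = [t for g in genes for t in g.transcripts]
        self._boundaries: dict[tuple[str, str], np.ndarray] = {}
        bsets: dict[tuple[str, str], set[int]] = {}
        for t in self.transcripts:
            bs = bsets.setdefault((t.chrom, t.strand), set())
            for (s, e) in t.exons:
                bs.add(s)
                bs.add(e)
        for key, vals in bsets.items():
            self._boundaries[key] = np.array(sorted(vals), dtype=np.int64)
        if validate:
            self.validate_partition()

    # -- derived interval sets -------------------------------------------

    def exonic_intervals(self, chrom: str, strand: str | None = None) -> list[tuple[int, int]]:
        ivs = [
            (s, e)
            for t in self.transcripts
            if t.chrom == chrom and (strand is None or t.strand == strand)
            for (s, e) in t.exons
        ]
        return _merge(ivs)

    def intronic_intervals(self, chrom: str, strand: str | None = None) -> list[tuple[int, int]]:
        ivs = [
            iv
            for t in self.transcripts
            if t.chrom == chrom and (strand is None or t.strand == strand)
            for iv in t.introns
        ]
        return _merge(ivs)

    def gene_spans(self, chrom: str) -> list[tuple[int, int]]:
        return _merge([g.span for g in self.genes if g.chrom == chrom])

    def intergenic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Complement of the (unstranded) union of gene spans."""
        n = self.chrom_lengths[chrom]
        out, prev = [], 0
        for (s, e) in self.gene_spans(chrom):
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < n:
            out.append((prev, n))
        return out

    # -- boundary queries -------------------------------------------------

    def boundary_set(self, chrom: str, strand: str) -> np.ndarray:
        return self._boundaries.get((chrom, strand), np.empty(0, dtype=np.int64))

    def boundary_distance(
        self, chrom: str, strand: str, coordinate: int, strand_aware: bool = True
    ) -> float:
        """nt distance from `coordinate` to the nearest exon boundary.

        Returns +inf when no boundary exists on the chromosome (and strand,
        if strand_aware).  0 iff the coordinate is itself a boundary.
        """
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= coordinate <= self.chrom_lengths[chrom]):
            raise IndexError(f"coordinate {coordinate} outside {chrom}")
        if strand_aware:
            arrs = [self.boundary_set(chrom, strand)]
        else:
            arrs = [self.boundary_set(chrom, s) for s in "+-"]
        best = math.inf
        for arr in arrs:
            if arr.size == 0:
                continue
            i = int(np.searchsorted(arr, coordinate))
            for j in (i - 1, i):
                if 0 <= j < arr.size:
                    best = min(best, abs(int(arr[j]) - coordinate))
        return best

    # -- invariants --------------------------------------------------------

    def validate_partition(self) -> None:
        """Exonic ∪ intronic ∪ intergenic must tile each chromosome exactly.

        Genic features must additionally be disjoint per strand (exon vs
        intron); overlapping gene models violate this and are rejected.
        """
        for chrom, n in self.chrom_lengths.items():
            for strand in "+-":
                ex = self.exonic_intervals(chrom, strand)
                inn = self.intronic_intervals(chrom, strand)
                if _overlap_any(ex, inn):
                    raise ValueError(
                        f"exonic and intronic intervals overlap on {chrom}{strand}"
                    )
            covered = _merge(
                self.exonic_intervals(chrom)
                + self.intronic_intervals(chrom)
                + self.intergenic_intervals(chrom)
            )
            if covered != [(0, n)]:
                raise ValueError(f"intervals do not partition {chrom}: {covered[:5]} ...")

    # -- GTF round trip ----------------------------------------------------

    def to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                for t in g.transcripts:
                    for (s, e) in t.exons:
                        attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                        fh.write(
                            f"{g.chrom}\tcircat\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                        )

    def to_bed(self, path) -> None:
        """Derived intervals (exon/intron/intergenic) as BED6-style lines."""
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                for strand in "+-":
                    for kind, ivs in (
                        ("exon", self.exonic_intervals(chrom, strand)),
                        ("intron", self.intronic_intervals(chrom, strand)),
                    ):
                        for (s, e) in ivs:
                            fh.write(f"{chrom}\t{s}\t{e}\t{kind}\t0\t{strand}\n")
                for (s, e) in self.intergenic_intervals(chrom):
                    fh.write(f"{chrom}\t{s}\t{e}\tintergenic\t0\t.\n")


def load_annotation(path, genome: Genome, validate: bool = True) -> GeneAnnotation:
    """Load a GTF (gene_id/transcript_id attributes) against a genome."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    tx: dict[str, Transcript] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = feat.attributes["gene_id"][0]
        t_id = feat.attributes["transcript_id"][0]
        if feat.seqid not in genome:
            raise ValueError(f"feature on chromosome {feat.seqid!r} absent from genome")
        start, end = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
        if end > genome.lengths[feat.seqid]:
            raise ValueError(f"exon {t_id}:{start}-{end} extends past end of {feat.seqid}")
        if t_id not in tx:
            tx[t_id] = Transcript(t_id, gene_id, feat.seqid, feat.strand, [])
            g = genes.setdefault(gene_id, Gene(gene_id, feat.seqid, feat.strand))
            g.transcripts.append(tx[t_id])
        tx[t_id].exons.append((start, end))
    for t in tx.values():
        t.__post_init__()  # re-sort and re-check after accumulation
    return GeneAnnotation(list(genes.values()), genome, validate=validate)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _overlap_any(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            return True
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return False
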