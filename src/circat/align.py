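"""Back-fusion junction detection by split-read anchor alignment.

The detector works on paired-end stranded reads.  Reads that map end-to-end
to the genome (allowing a small mismatch budget) come from linear RNA and
are discarded.  For an unmapped read, a left and a right x-mer anchor are
extracted; if the left anchor places strictly downstream of the right anchor
on the same chromosome (the orientation-reversed geometry characteristic of
a back-spliced junction, and impossible for a forward splice), the split
point s is sought such that read[:s] aligns ending at the circle donor D and
read[s:] aligns starting at the circle acceptor A, with the combined
mismatch count within budget.  The mate must then map end-to-end inside
[A, D) — or, for circles shorter than the fragment, itself split-map to the
same junction ("rotated-circle" geometry).

Short homologous sequence at the two junction flanks makes several split
positions equally valid; the contiguous window of valid s values is recorded
and the smallest (leftmost) s is the canonical representative, so all reads
over one junction aggregate to a single (A, D).

No splice-signal information is used anywhere in detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference import Genome

log = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "AnchorHit",
    "Placement",
    "SplitAlignment",
    "GenomeIndex",
    "revcomp",
    "map_linear",
    "extract_anchors",
    "anchor_hits",
    "find_reversed_anchor_pairs",
    "resolve_split_point",
    "canonicalize",
    "mate_within_circle",
    "detect_read_pair",
    "detect_pairs",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class DetectionParams:
    """Tunables of the junction search (defaults follow the method's stated values)."""

    anchor_length: int = 20          # x: anchor k-mer size for 100 bp reads
    max_mismatches: int = 2          # budget per end-to-end map and per combined split
    max_span: int = 100_000          # upper bound on circle size D - A
    min_anchor_mapq: int = 40        # uniqueness threshold for both anchors
    mate_mode: str = "rotated"       # "rotated" | "strict"
    library: str = "fr-firststrand"  # dUTP: read 2 carries the transcript sense
    max_n_fraction: float = 0.10

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")
        if self.anchor_length < 18:
            raise ValueError("anchor_length must be >= 18 for the seeded search")
        if self.mate_mode not in ("rotated", "strict"):
            raise ValueError(f"unknown mate_mode {self.mate_mode!r}")
        if self.library not in ("fr-firststrand", "fr-secondstrand"):
            raise ValueError(f"unknown library layout {self.library!r}")


@dataclass(frozen=True)
class Placement:
    """End-to-end placement of a read sequence on the forward genome.

    `orient` is "+" when the read sequence itself matches the forward
    genome, "-" when its reverse complement does.
    """

    chrom: str
    orient: str
    start: int
    length: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class AnchorHit:
    chrom: str
    start: int
    mismatches: int
    uniqueness: int  # pseudo-MAPQ in [0, 60]


@dataclass(frozen=True)
class SplitAlignment:
    read_id: str
    chrom: str
    strand: str          # inferred circle strand
    acceptor: int        # A: circle 5' start, 0-based
    donor: int           # D: one past circle 3' end (half-open)
    split: int           # canonical split position in the oriented read
    shift_window: tuple[int, int]  # inclusive range of valid split positions
    mismatches: int
    mate_flag: str = "interior"    # "interior" | "rotated"

    @property
    def span(self) -> int:
        return self.donor - self.acceptor


class GenomeIndex:
    """Exact k-mer seed index over the forward genome.

    Two k-mer sizes are kept: a long seed for full-read placement and a
    short seed for the x-mer anchors.  Completeness under the mismatch
    budget follows from the pigeonhole principle: a query split into three
    segments with at most two mismatches leaves at least one segment exact,
    and that segment's leading k-mer is then an exact index hit.
    """

    def __init__(self, genome: Genome, k_linear: int = 12, k_anchor: int = 6):
        self.genome = genome
        self.k_linear = k_linear
        self.k_anchor = k_anchor
        self.linear: dict[str, list[tuple[str, int]]] = {}
        self.anchor: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.chromosomes.items():
            for k, table in ((k_linear, self.linear), (k_anchor, self.anchor)):
                for i in range(len(seq) - k + 1):
                    table.setdefault(seq[i : i + k], []).append((chrom, i))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def map_linear(
    read: str, genome: Genome, index: GenomeIndex, params: DetectionParams
) -> Placement | None:
    """Best-effort contiguous end-to-end placement; None if unmappable.

    Reads with more than `max_n_fraction` N bases are classified unmappable
    without search.  Search stops at the first placement within the
    mismatch budget (existence is what matters: such reads are linear).
    """
    L = len(read)
    if L < 3 * index.k_linear:
        return None
    if read.count("N") > params.max_n_fraction * L:
        log.debug("read with >%.0f%% N classified unmappable", params.max_n_fraction * 100)
        return None
    seg = L // 3
    offsets = (0, seg, 2 * seg)
    for orient in "+-":
        seq = read if orient == "+" else revcomp(read)
        arr = _encode(seq)
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for chrom, pos in index.linear.get(seq[off : off + index.k_linear], ()):
                start = pos - off
                if start < 0 or start + L > genome.lengths[chrom]:
                    continue
                key = (chrom, start)
                if key in seen:
                    continue
                seen.add(key)
                mm = _hamming(arr, genome.array(chrom)[start : start + L])
                if mm <= params.max_mismatches:
                    return Placement(chrom, orient, start, L, mm)
    return None


def extract_anchors(read: str, x: int) -> tuple[str, str] | None:
    """Left/right x-mers of a read; None (skip) when the read is too short."""
    if len(read) < 2 * x:
        log.debug("read of length %d < 2x=%d skipped", len(read), 2 * x)
        return None
    return read[:x], read[len(read) - x :]


def anchor_hits(
    anchor: str, genome: Genome, index: GenomeIndex, params: DetectionParams
) -> list[AnchorHit]:
    """All forward-orientation placements of an anchor within the mismatch budget.

    Uniqueness pseudo-MAPQ: 40 when the best placement has at least two
    fewer mismatches than the runner-up, 0 when tied, linear in between
    (sole placements score 40).
    """
    x = len(anchor)
    k = index.k_anchor
    arr = _encode(anchor)
    found: dict[tuple[str, int], int] = {}
    for off in (0, k, 2 * k):
        for chrom, pos in index.anchor.get(anchor[off : off + k], ()):
            start = pos - off
            if start < 0 or start + x > genome.lengths[chrom]:
                continue
            if (chrom, start) in found:
                continue
            mm = _hamming(arr, genome.array(chrom)[start : start + x])
            if mm <= params.max_mismatches:
                found[(chrom, start)] = mm
    hits = []
    for (chrom, start), mm in found.items():
        others = [m for key, m in found.items() if key != (chrom, start)]
        second = min(others) if others else None
        if second is None:
            uniq = 40
        else:
            uniq = max(0, min(40, 20 * (second - mm)))
        hits.append(AnchorHit(chrom, start, mm, uniq))
    return hits


def find_reversed_anchor_pairs(
    left_hits: list[AnchorHit],
    right_hits: list[AnchorHit],
    params: DetectionParams,
    read_length: int,
) -> list[tuple[AnchorHit, AnchorHit]]:
    """Same-chromosome pairs with the left anchor strictly downstream.

    The implied circle span is fixed by the pair geometry:
    D - A = left.start - right.start + (L - x); it must be positive and at
    most max_span.  Both anchors must clear the uniqueness threshold.
    """
    x = params.anchor_length
    pairs = []
    for hl in left_hits:
        if hl.uniqueness < params.min_anchor_mapq:
            continue
        for hr in right_hits:
            if hr.uniqueness < params.min_anchor_mapq:
                continue
            if hl.chrom != hr.chrom or hl.start <= hr.start:
                continue
            span = hl.start - hr.start + (read_length - x)
            if 0 < span <= params.max_span:
                pairs.append((hl, hr))
    return pairs


def resolve_split_point(
    read: str,
    genome: Genome,
    pair: tuple[AnchorHit, AnchorHit],
    params: DetectionParams,
):
    """Enumerate split positions s in [x, L-x] for one anchor pair.

    For a split at s the prefix read[:s] aligns at [left.start, left.start+s)
    (so the donor is D = left.start + s) and the suffix read[s:] aligns
    ending at right.start + x (so the acceptor is A = right.start + x - L + s).
    Prefix mismatches are a cumulative sum from the left and suffix
    mismatches a cumulative sum from the right, so all s are scored in O(L).

    Returns (acceptor, donor, split, shift_window, mismatches) for the
    canonical (leftmost) valid split, or None.
    """
    hl, hr = pair
    L = len(read)
    x = params.anchor_length
    garr = genome.array(hl.chrom)
    n = garr.size
    rarr = _encode(read)

    # prefix comparison: read[i] vs genome[left.start + i]
    pl = min(L, n - hl.start)
    neq_p = np.ones(L, dtype=np.int64)
    neq_p[:pl] = garr[hl.start : hl.start + pl] != rarr[:pl]
    pref = np.concatenate(([0], np.cumsum(neq_p)))  # pref[s] = mismatches of read[:s]

    # suffix comparison: read[i] vs genome[base + i], base = right.start + x - L
    base = hr.start + x - L
    neq_s = np.ones(L, dtype=np.int64)
    lo = max(0, -base)
    hi = min(L, n - base)
    if hi > lo:
        neq_s[lo:hi] = garr[base + lo : base + hi] != rarr[lo:hi]
    suf = np.concatenate((np.cumsum(neq_s[::-1])[::-1], [0]))  # suf[s] = mism. of read[s:]

    mm_by_s = {}
    for s in range(x, L - x + 1):
        A = base + s
        D = hl.start + s
        if A < 0 or D > n or not (0 < D - A <= params.max_span):
            continue
        mm = int(pref[s] + suf[s])
        if mm <= params.max_mismatches:
            mm_by_s[s] = mm
    if not mm_by_s:
        return None
    # shifts within the budget but with extra mismatches are not junction-flank
    # homology; the shift window is the tie class of minimal-mismatch splits
    best = min(mm_by_s.values())
    valid = [s for s, mm in mm_by_s.items() if mm == best]
    s_canon, window = canonicalize(valid)
    return (base + s_canon, hl.start + s_canon, s_canon, window, best)


def canonicalize(valid_s: list[int]) -> tuple[int, tuple[int, int]]:
    """Smallest valid split (leftmost rule); warns on a non-contiguous set.

    Split-position ambiguity arises from junction-flank homology, which
    shifts (A, D) in lockstep with s — the leftmost s therefore maps every
    read over one junction to the same canonical coordinates.
    """
    if not valid_s:
        raise ValueError("canonicalize requires at least one valid split")
    vs = sorted(valid_s)
    if vs[-1] - vs[0] != len(vs) - 1:
        log.warning("non-contiguous valid split set %s; keeping smallest", vs)
    return vs[0], (vs[0], vs[-1])


def _split_align_oriented(
    seq: str, genome: Genome, index: GenomeIndex, params: DetectionParams
):
    """Try to split-map one oriented read sequence.

    Returns (chrom, A, D, s, window, mismatches) or None.  When several
    anchor pairs yield equally good but distinct junctions the read is
    ambiguous and rejected.
    """
    anchors = extract_anchors(seq, params.anchor_length)
    if anchors is None:
        return None
    left, right = anchors
    lh = anchor_hits(left, genome, index, params)
    rh = anchor_hits(right, genome, index, params)
    results = []
    for pair in find_reversed_anchor_pairs(lh, rh, params, len(seq)):
        res = resolve_split_point(seq, genome, pair, params)
        if res is not None:
            results.append((pair[0].chrom, *res))
    if not results:
        return None
    best = min(r[5] for r in results)
    top = {(r[0], r[1], r[2]): r for r in results if r[5] == best}
    if len(top) > 1:
        log.debug("ambiguous split read (%d equally good junctions); dropped", len(top))
        return None
    return next(iter(top.values()))


def _circle_strand(split_mate: int, orient: str, library: str) -> str:
    """Circle strand from which mate split-mapped and in which orientation.

    Under fr-firststrand (dUTP) read 2 carries the transcript sense: if
    read 2 matches the forward genome as-is the circle is on '+'.  Read 1
    is the antisense mate, so its orientations invert.  fr-secondstrand
    swaps the roles.
    """
    sense_mate = 2 if library == "fr-firststrand" else 1
    if split_mate == sense_mate:
        return "+" if orient == "+" else "-"
    return "-" if orient == "+" else "+"


def mate_within_circle(
    mate: str,
    genome: Genome,
    index: GenomeIndex,
    chrom: str,
    acceptor: int,
    donor: int,
    expected_orient: str,
    params: DetectionParams,
    placement: Placement | None = None,
) -> str | None:
    """Check the mate-pair constraint for a candidate junction.

    Returns "interior" when the mate maps end-to-end inside [A, D) in the
    orientation consistent with an FR library, "rotated" when the mate
    itself split-maps to the same canonical junction (circles shorter than
    the fragment; only in mate_mode="rotated"), and None otherwise.
    """
    p = placement if placement is not None else map_linear(mate, genome, index, params)
    if p is not None:
        if (
            p.chrom == chrom
            and p.orient == expected_orient
            and acceptor <= p.start
            and p.end <= donor
        ):
            return "interior"
        return None
    if params.mate_mode == "rotated":
        oseq = mate if expected_orient == "+" else revcomp(mate)
        res = _split_align_oriented(oseq, genome, index, params)
        if res is not None and res[0] == chrom and res[1] == acceptor and res[2] == donor:
            return "rotated"
    return None


def detect_read_pair(
    read_id: str,
    seq1: str,
    seq2: str,
    genome: Genome,
    index: GenomeIndex,
    params: DetectionParams,
) -> SplitAlignment | None:
    """Full per-pair decision: linear filter, split mapping, mate constraint."""
    p1 = map_linear(seq1, genome, index, params)
    p2 = map_linear(seq2, genome, index, params)
    if p1 is not None and p2 is not None:
        return None  # linear RNA

    candidates = []
    for mate_idx, seq, own_p in ((1, seq1, p1), (2, seq2, p2)):
        if own_p is not None:
            continue  # this mate maps linearly; not a split candidate
        if len(seq) < 2 * params.anchor_length:
            continue
        for orient in "+-":
            oseq = seq if orient == "+" else revcomp(seq)
            res = _split_align_oriented(oseq, genome, index, params)
            if res is not None:
                candidates.append((mate_idx, orient, res))
    if not candidates:
        return None
    best = min(c[2][5] for c in candidates)
    top = [c for c in candidates if c[2][5] == best]
    junctions = {(c[2][0], c[2][1], c[2][2]) for c in top}
    if len(junctions) > 1:
        return None  # ambiguous between distinct junctions / orientations
    mate_idx, orient, (chrom, A, D, s, window, mm) = top[0]

    other_seq = seq2 if mate_idx == 1 else seq1
    other_p = p2 if mate_idx == 1 else p1
    expected = "-" if orient == "+" else "+"
    flag = mate_within_circle(
        other_seq, genome, index, chrom, A, D, expected, params, placement=other_p
    )
    if flag is None:
        return None
    # oriented split position reported relative to the oriented (forward-matching) read
    strand = _circle_strand(mate_idx, orient, params.library)
    return SplitAlignment(read_id, chrom, strand, A, D, s, window, mm, flag)


def detect_pairs(
    pairs,
    genome: Genome,
    params: DetectionParams | None = None,
    index: GenomeIndex | None = None,
) -> tuple[list[SplitAlignment], dict]:
    """Run detection over an iterable of (read_id, seq1, seq2).

    Returns the accepted split alignments plus simple run statistics.
    """
    params = params or DetectionParams()
    index = index or GenomeIndex(genome)
    out: list[SplitAlignment] = []
    stats = {"pairs": 0, "bf_candidates": 0}
    for read_id, s1, s2 in pairs:
        stats["pairs"] += 1
        rec = detect_read_pair(read_id, s1.upper(), s2.upper(), genome, index, params)
        if rec is not None:
            out.append(rec)
            stats["bf_candidates"] += 1
    return out, stats
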