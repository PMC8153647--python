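# Methods

## Detection model

A circRNA leaves a single diagnostic footprint in RNA-seq: read pairs whose
one mate crosses the back-fusion (BF) junction.  Writing the circle as the
genomic interval [A, D) (0-based half-open, A = acceptor / circle 5' start,
D = donor / one past the 3' end), a junction-crossing read of length L cut
at split position s is

    read = genome[D-s : D] + genome[A : A+L-s]        (plus strand)

Detection inverts this construction without using splice signals or
annotation:

1. **Linear filter.** A read that aligns end-to-end with at most
   `max_mismatches` (default 2) substitutions is linear RNA and discarded.
   Reads with more than 10% N are set aside as unmappable.
2. **Anchors.** The terminal x-mers (x = 20 for 100 bp reads) of an
   unmapped read are placed on the genome.  A placement is accepted at
   ≤ `max_mismatches`; anchor *uniqueness* is a pseudo-MAPQ — 40 when the
   best placement has at least two fewer mismatches than the runner-up,
   0 on a tie, linear in between — and both anchors must reach
   `min_anchor_mapq` = 40.
3. **Reversed geometry.** Candidate pairs require the left anchor strictly
   downstream of the right anchor on the same chromosome (a forward splice
   gives the opposite order), with implied span D−A ≤ `max_span` (100 kb).
4. **Split resolution.** For a pair the donor/acceptor are linear in s
   (D = left_start + s, A = right_start + x − L + s), so prefix mismatches
   are one cumulative sum from the left and suffix mismatches one from the
   right: all s ∈ [x, L−x] are scored in O(L).  Splits within the budget
   but with more mismatches than the best split are *not* treated as
   alternatives — the shift window is the tie class of minimal-mismatch
   splits, which is exactly the junction-flank homology window.
5. **Canonical split.** The leftmost valid split is canonical.  Because the
   shift moves (A, D) in lockstep with s, every read over one junction maps
   to the same canonical coordinates regardless of where it was cut.  A
   purely positional tie-break is deliberate: the method uses no splice
   signal, so a GT-AG-preferring tie-break would smuggle the signal back in
   (it exists behind no flag here; the catalog instead reports the signal
   as a feature of the whole window).
6. **Mate constraint.** The mate must align end-to-end inside [A, D) in the
   FR-consistent orientation.  Circles shorter than the fragment make that
   impossible — both mates cross the junction — so in the default
   `rotated` mode a mate that split-maps to the *same* canonical junction
   is accepted and flagged; `strict` mode disables this.

Reads whose best split alignment is tied between distinct junctions are
ambiguous and dropped.  The mismatch budget is applied per end-to-end
mapping and to the *combined* split alignment (the stricter reading of a
per-mapping budget), not per segment.

Strandedness follows the dUTP (fr-firststrand) convention: read 2 carries
the transcript sense, and either mate may be the split one.  The circle
strand falls out of which mate split-mapped and in which orientation.

### Anchor placement engine

An internal exact-seed index is the reference implementation: 12-mer seeds
for full-read placement and 6-mer seeds for anchors, with pigeonhole
completeness — a query split into three parts with ≤ 2 mismatches leaves at
least one part exact, and that part's leading seed is an exact hit.  All
candidate placements are then verified by Hamming count, so the search is
exhaustive within the budget.  One consequence: uniqueness is computed
among placements within the budget; a placement with budget+1 mismatches is
not enumerated and cannot demote a pseudo-MAPQ.  SAM-based adapters can be
layered on top (any placement source that provides the same contract
works); none is required.

## Catalog

Aggregation keys on (chromosome, strand, A, D); per-sample support counts
distinct read pairs; candidates below `min_support` = 2 in every sample are
dropped.  Classification measures the distance of A and D to the union of
all transcripts' exon boundaries on the same strand (`boundary_tolerance`
default 0 — exact; configurable; a strand-agnostic fallback exists because
no isoform-selection or strand rule is inherent to the classification).
Structures kept for the abundant set are the unambiguous ones — single
exon, single intron, adjacent exon+intron in either order, intergenic —
because junction reads alone cannot resolve the internal structure of a
multi-feature circle; anything wider is labelled `other` and excluded.

Junction features:

* **SHS** — forward arm f = max h with genome[A:A+h] == genome[D:D+h],
  backward arm b likewise upstream; length f+b, sequence genome[A−b:A+f].
  Arms are capped at 60 nt (observed SHS reach the mid-50s) and at the
  circle span.  Note that detected candidates always have b = 0: the
  canonical (leftmost) coordinates sit at the left edge of the homology
  window.  The f+b definition is the package's own convention for
  arbitrary coordinates.
* **Splice signal** — GT immediately 3' of D and AG immediately 5' of A
  (reverse-complemented for minus strand: AC before A, CT after D),
  evaluated at *every* shift of the homology window, since the signal is an
  attribute of the junction, not of one shift.  Canonical GT-AG only;
  GC-AG/AT-AC are not counted.
* **Flank complementarity** — longest exact reverse-complement match
  between [A−200, A) and [D, D+200), reported at ≥ 8 nt (long enough to
  suppress chance 4–7-mers; both knobs configurable), truncated at
  chromosome ends.
* **Nesting** — proper same-strand containments and host genes with ≥ 2
  candidates; host = any gene whose span contains [A, D), all recorded.

## Quantification and differential expression

SRPBM = count × 10⁹ / mapped_reads; it is invariant under joint rescaling
of counts and library sizes.  Abundance requires max per-sample count ≥ k
(default 5) and presence (count ≥ 1) in ≥ m samples (default 10);
"appears" is read as count ≥ 1.  Support thresholds appear twice on
purpose: ≥ 2 reads at detection, ≥ 5 at the abundance stage.

The rank-sum test uses midranks.  The exact path enumerates all
C(n1+n2, min) rank splits whenever that count is ≤ 2×10⁵ (all group-size
pairs with min(n) ≤ 6 qualify by orders of magnitude); unconditional
enumeration for min(n) ≤ 12 is infeasible when the other group is large,
so the cap is the package's own bound.  Otherwise a tie-corrected normal
approximation **without** continuity correction is used: on negative-
binomial counts at n = 15/15 the uncorrected statistic sits closer to the
nominal 0.01 level, and both variants were verified inside the 3-MC-SE
calibration band before the generator conditions were frozen.  Significance
follows the raw p ≤ 0.01 rule to mirror the method's convention;
Benjamini–Hochberg adjusted values are always reported alongside so users
can apply FDR control instead.  Fold changes use a 0.1-SRPBM pseudocount in
both means (finite at zero expression; configurable).  All-zero rows are
p = 1, fold change 1.

External mRNA DE results enter through an adapter (`load_gene_de_table`):
q < 0.05 and fold change > 2 in either direction; the mRNA quantification
itself is out of scope.

## ceRNA association

The miRNA binding scanner is a transparent seed-and-extend scorer:
candidate sites are anchored by ≥ 6/7 Watson–Crick pairs against miRNA
positions 2–8, scored ungapped over the full miRNA with the 5' half
weighted double (+5/+10 per WC pair, +1 per G:U wobble outside the seed,
−4 per mismatch) plus a pair-count energy proxy (−3 G:C, −2 A:U, −1 G:U,
+0.5 mismatch).  The published predictor-default thresholds (score ≥ 140.0,
energy ≤ −1.0) are the configuration; bit-exact parity with any external
predictor's scores is a non-goal, and `load_external_targets` ingests such
output with identical thresholding.  T/U alphabets are interchangeable.

A triple (circRNA, miRNA, gene) is **associated** when the gene is DE in
the direction concordant with the circRNA, Spearman ρ > 0 and p < 0.01
(two-sided; a flag relaxes concordance, and one-sided testing is a
reasonable alternative reading of "positively correlated" — two-sided is
the default as the more conservative choice).  Spearman ρ is the Pearson
correlation of midranks; p uses the t approximation for n ≥ 10 and exact
permutation enumeration below that.  Zero-variance vectors make ρ
undefined; such pairs are reported not-associated.  miRNA family names are
kept distinct unless an explicit family map merges them.

## Synthetic data: what it emulates, and what not

`make_genome` draws i.i.d. uniform chromosomes (default 2 × 50 kb) and lays
out non-overlapping genes (default 1.2 per 10 kb) of 3–6 exons
(200–450 nt) and introns (300–700 nt) with strand-adjusted GT-AG terminal
dinucleotides, leaving ≥ 1 intergenic region per chromosome.  These sizes
give every structural category room for planted circles of ≥ 120 nt, the
minimum for the interior-mate fragment geometry at L = 100.

`plant_circles` realises a design of (class, structure, SHS, signal, flank
repeat) tuples by local genome edits: homology tracts written at both
junction flanks (content avoids G and T so no splice signal can arise
inside the tract; capped at 12 nt so 20-mer anchors stay unique), signal
dinucleotides planted or scrubbed at every shift of the window, inverted
repeats copied into the flanks, and a verify-and-repair loop that enforces
forward homology exactly h, backward homology 0 (planted coordinates are
therefore canonical) and the designed signal status.  Planted truth is
re-validated with the catalog module's own classifiers before any reads are
generated (self-consistency gate).

Reads follow the fragment model: junction pairs sample the split uniformly
in [25, L−25], the mate lands inside the circle (fragment = L + s + gap,
gap ∈ [5, 60]), and the junction-crossing role alternates between mates;
`simulate_rotated_pairs` produces the both-mates-cross geometry for circles
shorter than the fragment.  Substitution errors are i.i.d. (separate RNG
stream, so the fragment layout is invariant to the error rate); no indels,
matching the aligner's non-goal; constant base qualities; no PCR
duplicates, sequencer-specific error profiles or RNase-R chemistry.
Expression counts are negative-binomial (junction counts are
overdispersed); the ceRNA generator couples associated genes to the circRNA
through a latent Gaussian with tunable correlation.

Passing tests therefore demonstrate algorithmic correctness — exact
recovery, soundness against linear background, oracle equivalence,
statistical calibration — on repeat-free genomes with substitution-only
errors.  They do not demonstrate robustness to genomic repeats, indels,
splicing isoform complexity, or real library artefacts.

## Problem sizes and numerical choices

The bundled study runs 30 planted circles at depth 5–12 against a
50,000-pair linear background on 2 × 50 kb (detection < 15 s); oracle
comparisons use 1,000 random junctions (SHS) and 500 random junction reads
(exhaustive split search); calibration uses 10,000 null rows and 200
shifted replicates at n = 15/15.  Exact-test tie comparisons use a 1e-9
slack on rank sums to absorb float summation error; oracle equivalence is
asserted to 1e-12.  Non-contiguous valid-split sets (possible only through
sequencing errors) keep the smallest s and log a warning.

## Known limitations

* No indel handling at or near the junction; gapped anchors are out of scope.
* Multi-feature circle structures are deliberately not inferred.
* The uniqueness pseudo-MAPQ is meaningful only relative to the enumerated
  placement set (see above).
* The binding scanner is a scoring heuristic, not a thermodynamic folding
  model; site-level agreement with published predictors is approximate.
* GO/KEGG enrichment and wet-lab validation workflows are out of scope.
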