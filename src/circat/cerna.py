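"""circRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA) association.

A circRNA that sponges a miRNA relieves repression of that miRNA's mRNA
targets, so an associated gene should (i) share a binding miRNA with the
circRNA, (ii) be differentially expressed in the concordant direction, and
(iii) be positively rank-correlated with the circRNA across samples
(Spearman rho > 0, p < 0.01).

miRNA binding sites are found with a transparent seed-and-extend scanner:
candidate sites are anchored by Watson–Crick complementarity to the miRNA
seed (positions 2–8), extended by ungapped position-weighted scoring with
the miRNA 5' half weighted double and G:U wobble tolerated outside the
seed, plus a pair-count free-energy proxy.  The published default
thresholds (score 140.0, energy -1.0) are the configuration; an adapter
ingests site tables from external predictors with identical thresholding.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

__all__ = [
    "BindingSite",
    "MiRNATargetHit",
    "CeRNATriple",
    "scan_targets",
    "load_external_targets",
    "spearman",
    "associated_genes",
    "cascade_report",
]

SCORE_THRESHOLD = 140.0
ENERGY_THRESHOLD = -1.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in DNA alphabet


@dataclass(frozen=True)
class BindingSite:
    start: int   # target coordinates, 0-based half-open
    end: int
    score: float
    energy: float


@dataclass
class MiRNATargetHit:
    mirna_id: str
    target_id: str
    target_kind: str  # "circRNA" | "mRNA"
    sites: list[BindingSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _norm_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_targets(
    mirna: str,
    target: str,
    score_threshold: float = SCORE_THRESHOLD,
    energy_threshold: float = ENERGY_THRESHOLD,
    min_seed_match: int = 6,
) -> list[BindingSite]:
    """Seed-and-extend miRNA binding-site scan on one target sequence.

    The miRNA binds antiparallel: miRNA position i (1-based from the 5'
    end) pairs with target position t + 8 - i when the seed (positions
    2..8) sits on target window [t, t+7).  A window is a candidate when at
    least `min_seed_match` of the 7 seed positions are Watson–Crick paired;
    the duplex is then scored over the full miRNA length, +5 per WC pair
    (doubled for the miRNA 5' half), +1 per G:U wobble outside the seed,
    -4 per mismatch.  The energy proxy counts -3 (G:C), -2 (A:U/T) and
    -1 (G:U) per pair.  Overlapping passing sites merge keeping the best
    score.
    """
    m = _norm_seq(mirna)
    s = _norm_seq(target)
    M, N = len(m), len(s)
    if N < M:
        return []
    half = (M + 1) // 2
    sites: list[BindingSite] = []
    for tpos in range(0, N - 7 + 1):
        seed_wc = sum(
            (m[i - 1], s[tpos + 8 - i]) in _WC for i in range(2, 9)
        )
        if seed_wc < min_seed_match:
            continue
        score = 0.0
        energy = 0.0
        start = tpos + 8 - M  # target position paired with the miRNA 3' end
        for i in range(1, M + 1):
            tp = tpos + 8 - i
            if tp < 0 or tp >= N:
                score -= 4.0
                continue
            pair = (m[i - 1], s[tp])
            weight = 2.0 if i <= half else 1.0
            if pair in _WC:
                score += 5.0 * weight
                energy += -3.0 if pair[0] in "GC" else -2.0
            elif pair in _WOBBLE and not (2 <= i <= 8):
                score += 1.0
                energy += -1.0
            else:
                score -= 4.0
                energy += 0.5
        if score >= score_threshold and energy <= energy_threshold:
            sites.append(BindingSite(max(0, start), tpos + 7, score, energy))
    return _merge_sites(sites)


def _merge_sites(sites: list[BindingSite]) -> list[BindingSite]:
    if not sites:
        return []
    sites = sorted(sites, key=lambda x: (x.start, -x.score))
    out = [sites[0]]
    for site in sites[1:]:
        last = out[-1]
        if site.start < last.end:
            if site.score > last.score:
                out[-1] = site
        else:
            out.append(site)
    return out


def scan_target_files(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str,
    score_threshold: float = SCORE_THRESHOLD,
    energy_threshold: float = ENERGY_THRESHOLD,
) -> list[MiRNATargetHit]:
    """Scan every miRNA against every target sequence; keep non-empty hits."""
    hits = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            sites = scan_targets(mseq, tseq, score_threshold, energy_threshold)
            if sites:
                hits.append(MiRNATargetHit(mid, tid, target_kind, sites))
    return hits


def load_external_targets(
    path,
    target_kind: str = "mRNA",
    score_threshold: float = SCORE_THRESHOLD,
    energy_threshold: float = ENERGY_THRESHOLD,
) -> list[MiRNATargetHit]:
    """Adapter for external predictor output (TSV).

    Required columns: mirna, target, position, score, energy.  Thresholds
    are applied exactly as for the internal scanner; duplicate
    (mirna, target, position) rows are collapsed.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna", "target", "position", "score", "energy"):
        if col not in df.columns:
            raise ValueError(f"target table missing required column {col!r}")
    for idx, row in df.iterrows():
        try:
            float(row["score"]), float(row["energy"]), int(row["position"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row at line {idx + 2} of {path}: {exc}") from exc
    df = df.drop_duplicates(subset=["mirna", "target", "position"])
    df = df[(df["score"] >= score_threshold) & (df["energy"] <= energy_threshold)]
    out: dict[tuple[str, str], MiRNATargetHit] = {}
    for _, r in df.iterrows():
        key = (str(r["mirna"]), str(r["target"]))
        hit = out.setdefault(key, MiRNATargetHit(key[0], key[1], target_kind))
        pos = int(r["position"])
        hit.sites.append(BindingSite(pos, pos, float(r["score"]), float(r["energy"])))
    return list(out.values())


def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with midranks and a two-sided p-value.

    rho is the Pearson correlation of midranks (tie-robust).  For
    n >= exact_below the p-value uses the t approximation with n-2 degrees
    of freedom; below that the exact permutation null over all n!
    orderings is enumerated.  Zero variance in either vector makes rho
    undefined: (nan, nan) is returned and the pair is treated as
    not-associated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        log.debug("zero variance in a vector; Spearman undefined")
        return float("nan"), float("nan")
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    if n >= exact_below:
        rho_c = min(1.0 - 1e-15, max(-1.0 + 1e-15, rho))
        tstat = rho_c * math.sqrt((n - 2) / (1.0 - rho_c * rho_c))
        return rho, float(2.0 * t_dist.sf(abs(tstat), n - 2))
    # exact permutation: rho is monotone in sum(rx * perm(ry))
    rxc = rx - rx.mean()
    obs = abs(float(rxc @ ry))
    perms = np.array(list(itertools.permutations(ry)))
    stats = np.abs(perms @ rxc)
    p = float((stats >= obs - 1e-9).mean())
    return rho, p


@dataclass
class CeRNATriple:
    circ_id: str
    mirna_id: str
    gene_id: str
    n_circ_sites: int
    gene_is_de: bool
    gene_direction: str
    rho: float
    p_value: float
    associated: bool


def associated_genes(
    circ_id: str,
    circ_direction: str,
    circ_hits: list[MiRNATargetHit],
    gene_hits: list[MiRNATargetHit],
    de_genes: pd.DataFrame,
    circ_expression: pd.Series,
    gene_expression: pd.DataFrame,
    rho_threshold: float = 0.0,
    p_threshold: float = 0.01,
    require_concordance: bool = True,
) -> list[CeRNATriple]:
    """Emit (circRNA, miRNA, gene) triples and flag associated genes.

    A triple is associated when the gene is DE in the direction concordant
    with the circRNA (the positive-regulation ceRNA logic), rho exceeds
    `rho_threshold` and p is below `p_threshold`.  `de_genes` must carry
    gene_id / is_de / direction columns (see load_gene_de_table).
    """
    de = de_genes.set_index("gene_id")
    circ_mirnas = {h.mirna_id: h for h in circ_hits if h.target_id == circ_id and h.sites}
    triples = []
    for h in gene_hits:
        if h.mirna_id not in circ_mirnas or not h.sites:
            continue
        gene = h.target_id
        if gene not in de.index or gene not in gene_expression.index:
            continue
        gexp = gene_expression.loc[gene]
        if list(gexp.index) != list(circ_expression.index):
            raise ValueError("circRNA and gene expression sample sets disagree")
        rho, p = spearman(circ_expression.to_numpy(), gexp.to_numpy())
        is_de = bool(de.loc[gene, "is_de"])
        direction = str(de.loc[gene, "direction"])
        concordant = (not require_concordance) or (direction == circ_direction)
        assoc = (
            is_de
            and concordant
            and not math.isnan(rho)
            and rho > rho_threshold
            and p < p_threshold
        )
        triples.append(
            CeRNATriple(
                circ_id, h.mirna_id, gene,
                circ_mirnas[h.mirna_id].n_sites,
                is_de, direction, rho, p, assoc,
            )
        )
    return triples


def cascade_report(triples: list[CeRNATriple]) -> pd.DataFrame:
    """Per (circRNA, miRNA) summary: circRNA binding sites, mediated targets
    out of the miRNA's total targets in the triple set."""
    if not triples:
        return pd.DataFrame(
            columns=["circ_id", "mirna_id", "n_circ_sites", "mediated_targets",
                     "total_targets", "summary"]
        )
    rows = []
    keyfn = lambda t: (t.circ_id, t.mirna_id)
    for (cid, mid), grp in itertools.groupby(sorted(triples, key=keyfn), key=keyfn):
        grp = list(grp)
        mediated = sum(t.associated for t in grp)
        total = len(grp)
        rows.append(
            {
                "circ_id": cid,
                "mirna_id": mid,
                "n_circ_sites": grp[0].n_circ_sites,
                "mediated_targets": mediated,
                "total_targets": total,
                "summary": f"{mediated} out of {total} targets",
            }
        )
    return pd.DataFrame(rows)


def triples_to_frame(triples: list[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [t.circ_id for t in triples],
            "mirna_id": [t.mirna_id for t in triples],
            "gene_id": [t.gene_id for t in triples],
            "n_circ_sites": [t.n_circ_sites for t in triples],
            "gene_is_de": [t.gene_is_de for t in triples],
            "gene_direction": [t.gene_direction for t in triples],
            "rho": [t.rho for t in triples],
            "p_value": [t.p_value for t in triples],
            "associated": [t.associated for t in triples],
        }
    )
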