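"""SRPBM quantification, abundance filtering and rank-sum differential expression.

Digital circRNA expression is the number of read pairs split-mapped to the
back-fusion point.  Counts are normalised to spliced reads per billion
mappings: SRPBM = count * 1e9 / mapped_reads.  Abundant circRNAs must reach
k reads in at least one sample and appear (count >= 1) in at least m
samples.  Group differences are tested with the two-sided Wilcoxon–Mann–
Whitney rank-sum test: full enumeration of rank splits when the combination
count is small, a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "DEResult",
    "srpbm",
    "abundance_filter",
    "ranksum_test",
    "differential_expression",
    "load_gene_de_table",
]

# exact enumeration is used while C(n1+n2, min(n1,n2)) stays below this cap
_EXACT_CAP = 200_000


@dataclass
class FilterParams:
    min_reads: int = 5    # k: max per-sample support must reach this
    min_samples: int = 10  # m: number of samples with count >= 1
    de_alpha: float = 0.01

    def __post_init__(self):
        if self.min_reads < 1 or self.min_samples < 1:
            raise ValueError("min_reads and min_samples must be >= 1")
        if not (0 < self.de_alpha < 1):
            raise ValueError("de_alpha must be in (0, 1)")


class ExpressionMatrix:
    """circRNA x sample count matrix with library sizes and group labels."""

    def __init__(self, counts: pd.DataFrame, mapped_reads: pd.Series, groups: pd.Series):
        counts = counts.astype(np.int64)
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(mapped_reads.index)
        if missing:
            raise ValueError(f"samples missing mapped-read totals: {sorted(missing)}")
        missing = set(counts.columns) - set(groups.index)
        if missing:
            raise ValueError(f"samples missing group labels: {sorted(missing)}")
        mapped_reads = mapped_reads.loc[counts.columns]
        if (mapped_reads <= 0).any():
            raise ValueError("mapped-read totals must be positive")
        self.counts = counts
        self.mapped_reads = mapped_reads.astype(np.int64)
        self.groups = groups.loc[counts.columns].astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def srpbm(self) -> pd.DataFrame:
        return self.counts * 1e9 / self.mapped_reads

    def subset(self, circ_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(circ_ids)], self.mapped_reads, self.groups)

    # -- TSV interchange ---------------------------------------------------

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("circ_id").to_csv(counts_path, sep="\t")
        pd.DataFrame(
            {"sample": self.samples,
             "group": self.groups.values,
             "mapped_reads": self.mapped_reads.values}
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        for col in ("sample", "group", "mapped_reads"):
            if col not in sheet.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        sheet = sheet.set_index("sample")
        return cls(counts, sheet["mapped_reads"], sheet["group"])


def srpbm(count: float, mapped_reads: float) -> float:
    """Spliced reads per billion mappings: count * 1e9 / mapped_reads."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    return count * 1e9 / mapped_reads


def abundance_filter(matrix: ExpressionMatrix, params: FilterParams | None = None) -> list[str]:
    """IDs whose max count >= k and which appear (count >= 1) in >= m samples."""
    params = params or FilterParams()
    c = matrix.counts
    ok = (c.max(axis=1) >= params.min_reads) & ((c >= 1).sum(axis=1) >= params.min_samples)
    return list(c.index[ok])


def ranksum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test on two samples.

    Returns (W, p) where W is the rank sum of group A under midranks.
    The null distribution is enumerated exactly over all C(n1+n2, n1)
    equally likely rank assignments when that count is small; otherwise a
    tie-corrected normal approximation (no continuity correction) is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1, n2 = a.size, b.size
    n = n1 + n2
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    if np.all(pooled == pooled[0]):
        return w, 1.0
    if math.comb(n, min(n1, n2)) <= _EXACT_CAP:
        # enumerate rank splits of the smaller group for speed; the test is
        # symmetric so |W - mu| is identical from either side
        k = min(n1, n2)
        mu_k = k * (n + 1) / 2.0
        obs = abs((ranks[:n1].sum() if n1 == k else ranks[n1:].sum()) - mu_k)
        hits = total = 0
        for comb in itertools.combinations(range(n), k):
            total += 1
            if abs(ranks[list(comb)].sum() - mu_k) >= obs - 1e-9:
                hits += 1
        return w, hits / total
    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(var)
    return w, float(2.0 * norm.sf(abs(z)))


@dataclass
class DEResult:
    circ_id: str
    mean_srpbm_a: float
    mean_srpbm_b: float
    fold_change: float
    direction: str  # "up" = higher in group A
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    params: FilterParams | None = None,
    pseudocount: float = 0.1,
) -> list[DEResult]:
    """Rank-sum DE between two sample groups on SRPBM values.

    Significance follows the raw p <= de_alpha rule; Benjamini–Hochberg
    adjusted p-values are reported alongside so FDR control can be applied
    by the caller.  Fold change uses a pseudocount of `pseudocount` SRPBM
    in both means to remain finite at zero expression.
    """
    params = params or FilterParams()
    s = matrix.srpbm()
    cols_a = [c for c in matrix.samples if matrix.groups[c] == group_a]
    cols_b = [c for c in matrix.samples if matrix.groups[c] == group_b]
    if not cols_a or not cols_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    rows = []
    for circ_id in s.index:
        va = s.loc[circ_id, cols_a].to_numpy(dtype=float)
        vb = s.loc[circ_id, cols_b].to_numpy(dtype=float)
        if np.all(va == 0) and np.all(vb == 0):
            stat, p = float(len(va) * (len(va) + len(vb) + 1) / 2.0), 1.0
        else:
            stat, p = ranksum_test(va, vb)
        ma, mb = float(va.mean()), float(vb.mean())
        fc = (ma + pseudocount) / (mb + pseudocount)
        rows.append((circ_id, ma, mb, fc, "up" if ma > mb else ("down" if ma < mb else "none"), stat, p))
    pvals = np.array([r[6] for r in rows])
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    return [
        DEResult(r[0], r[1], r[2], r[3], r[4], r[5], r[6], float(q), r[6] <= params.de_alpha)
        for r, q in zip(rows, padj)
    ]


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [r.circ_id for r in results],
            "mean_srpbm_a": [r.mean_srpbm_a for r in results],
            "mean_srpbm_b": [r.mean_srpbm_b for r in results],
            "fold_change": [r.fold_change for r in results],
            "direction": [r.direction for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )


def load_gene_de_table(
    path, q_threshold: float = 0.05, fc_threshold: float = 2.0
) -> pd.DataFrame:
    """Ingest an externally computed DE-gene table (TSV).

    Required columns: gene_id, fold_change, q_value.  A gene is flagged DE
    when q < q_threshold and the fold change exceeds fc_threshold in either
    direction (ratio > fc or < 1/fc).  Direction is derived from the ratio.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "fold_change", "q_value"):
        if col not in df.columns:
            raise ValueError(f"DE gene table missing required column {col!r}")
    fc = df["fold_change"].astype(float)
    df["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    df["is_de"] = (df["q_value"].astype(float) < q_threshold) & (
        (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    )
    return df
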