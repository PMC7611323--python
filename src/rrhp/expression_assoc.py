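"""5hmC-gene-expression association in the focal tissue.

RNA-seq gene counts are normalized with median-of-ratios size factors and a
log2(x + 1) transform, each site is joined to the expression of its nearest
gene, and the association structure is summarized three ways:

* a 3-variable PCA on (mean 5hmC, signed TSS distance, expression) using the
  correlation matrix, reporting loadings (variable-component correlations)
  and cos^2 representation quality;
* Spearman rank correlations;
* high/low-5hmC comparisons: within a region class (promoter, first exon,
  first intron) genes are split at the median of their 5hmC level and the two
  expression distributions are compared by a two-sample two-sided
  Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureAnnotation
from .rrhp_counts import CountMatrix

__all__ = [
    "PcaResult",
    "KsResult",
    "REGION_CLASSES",
    "size_factors",
    "normalized_expression",
    "build_association_table",
    "pca3",
    "spearman",
    "ks_two_sample",
    "high_low_5hmc_comparison",
]

REGION_CLASSES = ("promoter", "first_exon", "first_intron")
ASSOC_VARIABLES = ("mean_5hmc", "tss_distance", "expression")


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # 3, descending
    explained: np.ndarray            # fractions, sum to 1
    loadings: pd.DataFrame           # variables x components, var-PC correlations
    cos2: pd.DataFrame               # squared loadings; rows sum to 1

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "explained": self.explained.tolist(),
            "loadings": {v: self.loadings.loc[v].tolist() for v in self.loadings.index},
            "cos2": {v: self.cos2.loc[v].tolist() for v in self.cos2.index},
        }


@dataclass(frozen=True)
class KsResult:
    region_class: str
    d: float
    p: float
    n_high: int
    n_low: int
    quartiles_high: tuple[float, ...]
    quartiles_low: tuple[float, ...]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    Genes with a zero count in any sample are excluded from the reference
    geometric means; if no gene qualifies, factors fall back to column-sum
    ratios (flagged via the returned Series' ``.attrs['fallback']``).
    """
    counts = matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        logc = np.log(counts[allpos])
        log_geomean = logc.mean(axis=1)
        ratios = logc - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
        fallback = False
    else:
        colsum = counts.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError("cannot derive size factors: empty sample column")
        factors = colsum / np.exp(np.mean(np.log(colsum)))
        fallback = True
    out = pd.Series(factors, index=matrix.columns, name="size_factor")
    out.attrs["fallback"] = fallback
    return out


def normalized_expression(matrix: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Per-gene mean over samples of log2(count / size_factor + 1)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    scaled = matrix.div(factors, axis=1)
    return pd.Series(
        np.log2(scaled + 1.0).mean(axis=1), index=matrix.index, name="expression"
    )


def build_association_table(
    count_matrix: CountMatrix,
    annotations: Mapping[tuple, FeatureAnnotation],
    expression: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """One record per site: mean 5hmC (focal-tissue replicates), TSS distance
    and the nearest gene's normalized expression.

    Sites whose nearest gene is absent from ``expression`` (or that have no
    nearest gene) are dropped and tallied; one gene may back many records.
    """
    mean_counts = count_matrix.counts.mean(axis=1)
    rows = []
    n_dropped = 0
    for key in count_matrix.counts.index:
        ann = annotations.get(tuple(key))
        if ann is None:
            raise KeyError(f"site {key} has no annotation")
        if ann.gene_id is None or ann.gene_id not in expression.index:
            n_dropped += 1
            continue
        rows.append(
            {
                "chrom": key[0],
                "position": key[1],
                "strand": key[2],
                "mean_5hmc": float(mean_counts.loc[[key]].iloc[0]),
                "tss_distance": int(ann.tss_distance),
                "gene_id": ann.gene_id,
                "expression": float(expression.loc[ann.gene_id]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "position", "strand", "mean_5hmc", "tss_distance",
                 "gene_id", "expression"],
    )
    table.index = pd.Index(
        [(r.chrom, r.position, r.strand) for r in table.itertuples()], tupleize_cols=False
    )
    return table, {"n_dropped_no_expression": n_dropped, "n_records": len(table)}


def pca3(
    table: pd.DataFrame,
    log_5hmc: bool = False,
    abs_distance: bool = False,
) -> PcaResult:
    """Correlation-matrix PCA of (mean_5hmc, tss_distance, expression).

    Variables are z-scored (optionally log10(x+1)-transformed 5hmC and
    absolute distance first).  Loadings are variable-component correlations
    ``eigvec * sqrt(eigval)``; each component's largest-magnitude loading is
    made positive.  Eigenvalues sum to 3, cos^2 rows sum to 1.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 records for a 3-variable PCA")
    data = pd.DataFrame(
        {
            "mean_5hmc": np.log10(table["mean_5hmc"] + 1.0) if log_5hmc else table["mean_5hmc"],
            "tss_distance": table["tss_distance"].abs() if abs_distance else table["tss_distance"],
            "expression": table["expression"],
        }
    ).astype(float)
    sd = data.std(ddof=0)
    dead = [v for v in data.columns if sd[v] == 0]
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    z = (data - data.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)[None, :]
    for c in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(3)]
    loadings_df = pd.DataFrame(loadings, index=list(ASSOC_VARIABLES), columns=comp_names)
    cos2 = loadings_df ** 2
    return PcaResult(
        eigenvalues=eigval,
        explained=eigval / eigval.sum(),
        loadings=loadings_df,
        cos2=cos2,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided KS test.

    Exact p by enumeration when n_a * n_b <= 10,000, otherwise the asymptotic
    Kolmogorov distribution at effective size n_a n_b / (n_a + n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _region_mask(ann: FeatureAnnotation, region_class: str) -> bool:
    if region_class == "promoter":
        return ann.feature == "promoter"
    if region_class == "first_exon":
        return ann.feature == "exon" and ann.feature_index[0] == 1
    if region_class == "first_intron":
        return ann.feature == "intron" and ann.feature_index[0] == 1
    raise ValueError(f"unknown region class {region_class!r}; expected one of {REGION_CLASSES}")


def high_low_5hmc_comparison(
    table: pd.DataFrame,
    annotations: Mapping[tuple, FeatureAnnotation],
    region_class: str,
    gene_agg: str = "max",
) -> KsResult:
    """Median-split genes by 5hmC within a region class; KS on expression.

    Sites are restricted to the region class, aggregated to genes by the max
    (or mean) of their mean 5hmC; genes at or below the median 5hmC form the
    low group, strictly above it the high group.  Quartile summaries of each
    group's expression are included for reporting.
    """
    keep = [k for k in table.index if _region_mask(annotations[tuple(k)], region_class)]
    if not keep:
        raise ValueError(f"no sites in region class {region_class!r}")
    sub = table.loc[keep]
    agg = {"max": "max", "mean": "mean"}[gene_agg]
    by_gene = sub.groupby("gene_id").agg(
        level=("mean_5hmc", agg), expression=("expression", "first")
    )
    med = float(by_gene["level"].median())
    high = by_gene[by_gene["level"] > med]
    low = by_gene[by_gene["level"] <= med]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"region class {region_class!r}: need >= 2 genes per group "
            f"(got high={len(high)}, low={len(low)})"
        )
    d, p = ks_two_sample(high["expression"].to_numpy(), low["expression"].to_numpy())
    qs = (0, 25, 50, 75, 100)
    return KsResult(
        region_class=region_class,
        d=d,
        p=p,
        n_high=len(high),
        n_low=len(low),
        quartiles_high=tuple(float(x) for x in np.percentile(high["expression"], qs)),
        quartiles_low=tuple(float(x) for x in np.percentile(low["expression"], qs)),
    )
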