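"""Empirical-Bayes moderated differential hydroxymethylation testing.

Per-site log2-CPM values are modelled by ordinary least squares under a
tissue-means design.  Residual variances are shrunk toward a common prior by
moments-matching a scaled inverse-chi-square (equivalently, assuming
``s^2 ~ s0^2 * F(d, d0)``), giving the moderated t-statistic

    t = (w' beta_hat) / (s_tilde * sqrt(w' (X'X)^-1 w)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

with d0 + d degrees of freedom (a normal reference in the full-shrinkage
limit d0 = inf; no moderation at all when d0 = 0).  Two-sided p-values are
Benjamini-Hochberg adjusted within each contrast and sites are called
hyper-/hypo-hydroxymethylated in the contrast's first tissue by the sign of
the log2 fold change at a strict q-value threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .rrhp_counts import CountMatrix, SampleInfo

__all__ = [
    "DesignMatrix",
    "Contrast",
    "FitResult",
    "VariancePrior",
    "make_design",
    "pairwise_contrasts",
    "log_cpm",
    "fit_linear_model",
    "estimate_variance_prior",
    "trigamma_inverse",
    "moderated_t",
    "bh_adjust",
    "call_dhmc",
    "run_differential",
    "DEFAULT_Q_THRESHOLDS",
]

#: contrast-specific q-value call thresholds (configurable everywhere they
#: are used); keys follow the <Tissue1>v<Tissue2> initial convention.
DEFAULT_Q_THRESHOLDS = {"MvL": 0.01, "MvP": 0.05, "LvP": 0.01}


@dataclass
class DesignMatrix:
    """Tissue-means parameterization: one indicator column per tissue."""

    X: np.ndarray
    tissues: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not np.all(self.X.sum(axis=1) == 1):
            raise ValueError("each sample must belong to exactly one tissue")

    @property
    def rank(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class Contrast:
    name: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights)) > 1e-12:
            raise ValueError(f"contrast {self.name}: weights must sum to 0")


@dataclass
class FitResult:
    coefficients: np.ndarray  # sites x columns, log2 scale
    s2: np.ndarray            # per-site residual variance
    df_resid: int
    design: DesignMatrix
    site_index: pd.Index


@dataclass(frozen=True)
class VariancePrior:
    d0: float     # prior degrees of freedom, may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (math.inf allowed)")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("s0_sq must be positive")


def make_design(samples: Sequence[SampleInfo]) -> DesignMatrix:
    tissues: list[str] = []
    for s in samples:
        if s.tissue not in tissues:
            tissues.append(s.tissue)
    X = np.zeros((len(samples), len(tissues)))
    for i, s in enumerate(samples):
        X[i, tissues.index(s.tissue)] = 1.0
    return DesignMatrix(X, tissues, [s.sample_id for s in samples])


def _contrast_name(t1: str, t2: str, tissues: Sequence[str]) -> str:
    initials = [t[0].upper() for t in tissues]
    if len(set(initials)) == len(tissues):
        return f"{t1[0].upper()}v{t2[0].upper()}"
    return f"{t1}_vs_{t2}"


def pairwise_contrasts(design: DesignMatrix) -> list[Contrast]:
    """All ordered tissue pairs in design order: first tissue gets weight +1."""
    out = []
    for i, t1 in enumerate(design.tissues):
        for j, t2 in enumerate(design.tissues):
            if j <= i:
                continue
            w = [0.0] * design.rank
            w[i], w[j] = 1.0, -1.0
            out.append(Contrast(_contrast_name(t1, t2, design.tissues), tuple(w)))
    return out


def log_cpm(matrix: CountMatrix, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts per million: ``log2((k + prior) / (lib_size + 1) * 1e6)``."""
    lib = matrix.library_sizes
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    y = (matrix.counts + prior_count).div(lib + 1.0, axis=1) * 1e6
    return np.log2(y)


def fit_linear_model(y: pd.DataFrame, design: DesignMatrix) -> FitResult:
    """Per-site OLS.  Under the means design, coefficients are tissue means."""
    n, k = design.X.shape
    if y.shape[1] != n:
        raise ValueError("y columns do not match design rows")
    if n <= k:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={k})")
    Y = y.to_numpy(dtype=float)
    X = design.X
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # sites x k
    resid = Y - beta @ X.T
    d = n - k
    s2 = (resid ** 2).sum(axis=1) / d
    return FitResult(coefficients=beta, s2=s2, df_resid=d, design=design, site_index=y.index)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, near-linear)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, d: int) -> VariancePrior:
    """Moments-matching fit of the variance prior from log residual variances.

    With z = log(s^2): var(z) - trigamma(d/2) = trigamma(d0/2) determines d0
    (infinite when the left side is <= 0), and mean(z) determines s0^2 via
    mean(z) = log(s0^2) + digamma(d/2) - log(d/2) - [digamma(d0/2) - log(d0/2)].
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) == 0:
        raise ValueError("all residual variances are zero; cannot estimate a prior")
    if len(pos) < 30:
        raise ValueError(f"need >= 30 positive residual variances, got {len(pos)}")
    z = np.log(pos)
    zbar = float(z.mean())
    zvar = float(z.var(ddof=1))
    evar = zvar - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        d0 = math.inf
        log_s0 = zbar - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    else:
        d0 = 2.0 * trigamma_inverse(evar)
        log_s0 = (
            zbar
            - float(special.digamma(d / 2.0))
            + math.log(d / 2.0)
            + float(special.digamma(d0 / 2.0))
            - math.log(d0 / 2.0)
        )
    return VariancePrior(d0=d0, s0_sq=float(np.exp(log_s0)))


def moderated_t(fit: FitResult, prior: VariancePrior, contrast: Contrast) -> pd.DataFrame:
    """Per-site logFC, moderated t, total df and two-sided p for one contrast.

    Sites where the posterior variance is exactly zero are assigned p = 0 and
    flagged ``degenerate`` rather than dropped.
    """
    w = np.asarray(contrast.weights, dtype=float)
    X = fit.design.X
    v_c = float(w @ np.linalg.inv(X.T @ X) @ w)
    logfc = fit.coefficients @ w
    d0, d = prior.d0, fit.df_resid
    if math.isinf(d0):
        s2_post = np.full_like(fit.s2, prior.s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s2_post = fit.s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * prior.s0_sq + d * fit.s2) / (d0 + d)
        df_total = float(d0 + d)
    se = np.sqrt(s2_post * v_c)
    degenerate = se == 0
    t = np.zeros_like(logfc)
    nz = ~degenerate
    t[nz] = logfc[nz] / se[nz]
    t[degenerate & (logfc != 0)] = np.sign(logfc[degenerate & (logfc != 0)]) * np.inf
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(degenerate, 0.0, p)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "df": df_total,
            "p": p,
            "degenerate": degenerate,
        },
        index=fit.site_index,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_dhmc(results: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    """Sites with q strictly below the threshold, with hyper/hypo direction.

    ``hyper`` means higher 5hmC in the contrast's first tissue (logFC > 0).
    """
    called = results[results["q"] < q_threshold].copy()
    called["direction"] = np.where(called["logFC"] > 0, "hyper", "hypo")
    return called


def run_differential(
    matrix: CountMatrix,
    contrasts: Sequence[Contrast] | None = None,
    prior_count: float = 0.5,
    prior: VariancePrior | None = None,
) -> tuple[dict[str, pd.DataFrame], VariancePrior]:
    """log-CPM -> OLS fit -> variance prior -> moderated t + BH per contrast."""
    design = make_design(matrix.samples)
    y = log_cpm(matrix, prior_count=prior_count)
    fit = fit_linear_model(y, design)
    if prior is None:
        prior = estimate_variance_prior(fit.s2, fit.df_resid)
    if contrasts is None:
        contrasts = pairwise_contrasts(design)
    results: dict[str, pd.DataFrame] = {}
    for c in contrasts:
        res = moderated_t(fit, prior, c)
        res["q"] = bh_adjust(res["p"].to_numpy())
        results[c.name] = res
    return results, prior


def write_differential_tsv(results: pd.DataFrame, path) -> None:
    out = results.copy()
    out.insert(0, "strand", [k[2] for k in out.index])
    out.insert(0, "position", [k[1] for k in out.index])
    out.insert(0, "chrom", [k[0] for k in out.index])
    if "direction" not in out.columns:
        out["direction"] = np.where(out["logFC"] > 0, "hyper", "hypo")
    out.to_csv(path, sep="\t", index=False)
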