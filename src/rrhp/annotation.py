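"""Genomic-feature annotation of CCGG sites and enrichment statistics.

Each site is assigned to the transcript whose TSS is nearest (minimal
absolute signed TSS distance, ties broken by smaller gene id) and then to one
feature class against *that* transcript, with precedence

    promoter > TTS > exon > intron > intergenic.

Distances are signed in transcript orientation: positive downstream of the
TSS, negative upstream.  Promoter and TTS windows default to (-1000, +100)
around the TSS and (-100, +1000) around the TES respectively.  Exons and
introns carry a (k, n) index in transcript orientation (k-th of n).

Enrichment of hyper- vs hypo-hydroxymethylated calls within a feature is a
two-sided Fisher exact test on the 2x2 table (direction x in/out of feature);
relative feature enrichment compares, per tissue, the feature composition of
the sites whose mean normalized 5hmC level is highest in that tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CcggSite, GenomeAnnotation, TranscriptModel

__all__ = [
    "FeatureAnnotation",
    "EnrichmentResult",
    "RelativeEnrichmentResult",
    "FEATURE_CLASSES",
    "signed_tss_distance",
    "signed_tes_distance",
    "annotate_site",
    "annotate_sites",
    "annotations_frame",
    "gene_level_sets",
    "fisher_exact_2x2",
    "feature_enrichment",
    "relative_feature_enrichment",
    "PROMOTER_WINDOW",
    "TTS_WINDOW",
]

FEATURE_CLASSES = ("promoter", "exon", "intron", "TTS", "intergenic")
PROMOTER_WINDOW = (-1000, 100)
TTS_WINDOW = (-100, 1000)


@dataclass(frozen=True)
class FeatureAnnotation:
    site: CcggSite
    feature: str
    feature_index: tuple[int, int] | None  # (k, n) for exon/intron
    gene_id: str | None
    tss_distance: int | None
    gene_description: str = ""

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature!r}")
        if (self.feature in ("exon", "intron")) != (self.feature_index is not None):
            raise ValueError("feature_index present iff feature is exon/intron")
        if self.feature_index is not None:
            k, n = self.feature_index
            if not (1 <= k <= n):
                raise ValueError(f"feature index {k}/{n} out of range")


@dataclass(frozen=True)
class EnrichmentResult:
    contrast: str
    feature: str
    n_hyper_in: int
    n_hyper_out: int
    n_hypo_in: int
    n_hypo_out: int
    odds_ratio: float
    p: float
    tier: str  # '', '*', '**', '***'


@dataclass(frozen=True)
class RelativeEnrichmentResult:
    tissue: str
    feature: str
    proportion_in_tissue: float
    mean_proportion_other_tissues: float
    relative_enrichment_pct: float


def signed_tss_distance(site: CcggSite, transcript: TranscriptModel) -> int:
    """Signed distance from the TSS, positive downstream in gene orientation."""
    if site.chrom != transcript.chrom:
        raise ValueError("site and transcript on different chromosomes")
    if transcript.strand == "+":
        return site.position - transcript.tss
    return transcript.tss - site.position


def signed_tes_distance(site: CcggSite, transcript: TranscriptModel) -> int:
    """Same sign convention applied to the transcription end site."""
    if transcript.strand == "+":
        return site.position - transcript.tes
    return transcript.tes - site.position


def _classify_against(
    site: CcggSite,
    tx: TranscriptModel,
    promoter_window: tuple[int, int],
    tts_window: tuple[int, int],
) -> tuple[str, tuple[int, int] | None]:
    d_tss = signed_tss_distance(site, tx)
    if promoter_window[0] <= d_tss <= promoter_window[1]:
        return "promoter", None
    d_tes = signed_tes_distance(site, tx)
    if tts_window[0] <= d_tes <= tts_window[1]:
        return "TTS", None
    for k, (s, e) in enumerate(tx.exons, start=1):
        if s <= site.position <= e:
            return "exon", (k, tx.n_exons)
    for k, (s, e) in enumerate(tx.introns(), start=1):
        if s <= site.position <= e:
            return "intron", (k, tx.n_exons - 1)
    return "intergenic", None


def annotate_site(
    site: CcggSite,
    annotation: GenomeAnnotation,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    tts_window: tuple[int, int] = TTS_WINDOW,
) -> FeatureAnnotation:
    """Nearest-TSS gene assignment plus feature class with precedence."""
    tx = annotation.nearest_by_tss(site.chrom, site.position)
    if tx is None:
        return FeatureAnnotation(site, "intergenic", None, None, None)
    feature, idx = _classify_against(site, tx, promoter_window, tts_window)
    return FeatureAnnotation(
        site,
        feature,
        idx,
        tx.gene_id,
        signed_tss_distance(site, tx),
        tx.description,
    )


def annotate_sites(
    sites: Iterable[CcggSite],
    annotation: GenomeAnnotation,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    tts_window: tuple[int, int] = TTS_WINDOW,
) -> dict[tuple, FeatureAnnotation]:
    """Annotate many sites; keyed by (chrom, position, strand) tuples."""
    out: dict[tuple, FeatureAnnotation] = {}
    for s in sites:
        s = CcggSite(*s)
        out[tuple(s)] = annotate_site(s, annotation, promoter_window, tts_window)
    return out


def annotations_frame(annotations: Mapping[tuple, FeatureAnnotation]) -> pd.DataFrame:
    """Tabular view (column layout mirrors the per-site report TSV)."""
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        idx = f"{a.feature_index[0]}/{a.feature_index[1]}" if a.feature_index else ""
        rows.append(
            {
                "chrom": a.site.chrom,
                "position": a.site.position,
                "strand": a.site.strand,
                "feature": a.feature,
                "feature_index": idx,
                "gene_id": a.gene_id if a.gene_id is not None else "",
                "tss_distance": a.tss_distance if a.tss_distance is not None else "",
                "gene_description": a.gene_description,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "position", "strand", "feature", "feature_index",
            "gene_id", "tss_distance", "gene_description",
        ],
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test; sample odds ratio (a*d)/(b*c).

    Degenerate margins give p = 1; a zero denominator with a nonzero
    numerator gives an infinite odds ratio, 0/0 gives NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def feature_enrichment(
    calls: pd.DataFrame,
    annotations: Mapping[tuple, FeatureAnnotation],
    contrast: str,
) -> list[EnrichmentResult]:
    """Per feature class, Fisher test of direction x (in/out of the feature).

    ``calls`` must carry a ``direction`` column and be indexed by site key
    tuples (the output of :func:`rrhp.differential.call_dhmc`).
    """
    if calls.empty:
        return []
    missing = [k for k in calls.index if k not in annotations]
    if missing:
        raise KeyError(f"{len(missing)} called site(s) lack annotations")
    features = pd.Series({k: annotations[k].feature for k in calls.index})
    hyper = calls["direction"] == "hyper"
    out = []
    for f in FEATURE_CLASSES:
        in_f = features.loc[calls.index] == f
        a = int((hyper & in_f).sum())
        b = int((hyper & ~in_f).sum())
        c = int((~hyper & in_f).sum())
        d = int((~hyper & ~in_f).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        out.append(EnrichmentResult(contrast, f, a, b, c, d, odds, p, _tier(p)))
    return out


def gene_level_sets(
    calls_by_contrast: Mapping[str, pd.DataFrame],
    annotations: Mapping[tuple, FeatureAnnotation],
    exclude_description_pattern: str | None = "uncharacterized",
) -> dict:
    """Gene-level hyper/hypo sets per contrast, plus cross-contrast overlaps.

    A gene is hyper (in the contrast's first tissue) when >= 1 called site
    with direction 'hyper' maps to it; genes may appear in both sets.  Sites
    mapping to genes whose description matches the exclusion pattern (default
    'uncharacterized', case-insensitive) are excluded and tallied.
    """
    per_contrast: dict[str, dict[str, set]] = {}
    n_excluded: dict[str, int] = {}
    for name, calls in calls_by_contrast.items():
        hyper: set[str] = set()
        hypo: set[str] = set()
        excluded = 0
        for key, row in calls.iterrows():
            ann = annotations[key]
            if ann.gene_id is None:
                continue
            if exclude_description_pattern and (
                exclude_description_pattern.lower() in ann.gene_description.lower()
            ):
                excluded += 1
                continue
            (hyper if row["direction"] == "hyper" else hypo).add(ann.gene_id)
        per_contrast[name] = {"hyper": hyper, "hypo": hypo, "both": hyper & hypo}
        n_excluded[name] = excluded
    names = list(per_contrast)
    pairwise = {}
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            pairwise[f"{n1}&{n2}"] = {
                d: per_contrast[n1][d] & per_contrast[n2][d] for d in ("hyper", "hypo")
            }
    return {
        "per_contrast": per_contrast,
        "pairwise_hyper_intersections": {k: v["hyper"] for k, v in pairwise.items()},
        "pairwise": pairwise,
        "n_excluded_uncharacterized": n_excluded,
    }


def relative_feature_enrichment(
    mean_levels: pd.DataFrame,
    features: Mapping[tuple, str],
) -> tuple[list[RelativeEnrichmentResult], dict]:
    """Relative enrichment of top-tissue DhmCs within each feature class.

    ``mean_levels`` is sites x tissues (mean normalized 5hmC per tissue, e.g.
    tissue means of log-CPM).  Each site's top tissue is the argmax of its
    row; exact ties are excluded and tallied.  For tissue t and feature f,

        rel_pct = 100 * (p_tf / mean over other tissues of p_.f - 1),

    where p_tf is the share of t-topped sites annotated to f.
    """
    if mean_levels.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    arr = mean_levels.to_numpy(dtype=float)
    top = arr.argmax(axis=1)
    is_tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    tissues = list(mean_levels.columns)
    props = pd.DataFrame(0.0, index=tissues, columns=list(FEATURE_CLASSES))
    counts = {t: 0 for t in tissues}
    for key, t_idx, tie in zip(mean_levels.index, top, is_tie):
        if tie:
            continue
        t = tissues[t_idx]
        counts[t] += 1
        props.loc[t, features[key]] += 1
    flagged_empty = [t for t in tissues if counts[t] == 0]
    for t in tissues:
        if counts[t]:
            props.loc[t] /= counts[t]
    results = []
    for t in tissues:
        if counts[t] == 0:
            continue
        others = [u for u in tissues if u != t and counts[u] > 0]
        for f in FEATURE_CLASSES:
            denom = float(np.mean([props.loc[u, f] for u in others])) if others else 0.0
            rel = 100.0 * (props.loc[t, f] / denom - 1.0) if denom > 0 else float("nan")
            results.append(
                RelativeEnrichmentResult(t, f, float(props.loc[t, f]), denom, rel)
            )
    report = {"n_ties_excluded": int(is_tie.sum()), "tissues_without_topped_sites": flagged_empty}
    return results, report
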