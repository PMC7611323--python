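"""Seeded generators for toy genomes, annotations, RRHP counts and expression.

The generator emulates the statistical structure of a three-tissue,
five-replicate RRHP study of the somatotropic axis (muscle, liver,
pituitary):

* a random genome with CCGG motifs planted at Poisson-spaced positions on a
  motif-free background (so the site catalogue is known exactly);
* non-overlapping gene models with valid exon chains, written as GFF3;
* per-site counts with lognormal baselines and negative-binomial noise
  (dispersion 0.1 by default), per-sample library-size factors, capture
  dropout at the 75% rate the assay achieves, and planted tissue-specific
  log2 fold changes;
* gene-expression counts optionally coupled (negatively by default, matching
  the association the assay revealed) to promoter / first-exon / first-intron
  5hmC.

Determinism: one :class:`numpy.random.SeedSequence` per run; each stage draws
from its own child stream in a fixed documented order (genome=0, annotation=1,
counts=2, expression=3), so partial re-runs are reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureAnnotation, annotate_sites
from .genome_io import (
    CcggSite,
    GenomeAnnotation,
    GenomeSequence,
    TranscriptModel,
)
from .rrhp_counts import CountMatrix, SampleInfo

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_annotation",
    "simulate_rrhp_counts",
    "simulate_expression",
    "simulate_study",
    "simulate_association_table",
    "gene_region_5hmc",
    "score_detection",
    "write_gff3",
    "matrix_to_read_starts",
]

_STAGE_GENOME, _STAGE_ANNOT, _STAGE_COUNTS, _STAGE_EXPR = range(4)
_CCGG = re.compile("CCGG")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the design of the emulated study where it states one
    (3 tissues x 5 replicates, 75% capture, dispersion-0.1 overdispersed
    counts around a mean of ~50 reads per captured site, planted |log2FC| = 2,
    negative promoter/first-intron/first-exon coupling to expression) and a
    desk-scale genome elsewhere.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 150_000
    ccgg_density: float = 2.5            # expected motifs per kb
    # annotation
    n_genes: int = 80
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (150, 700)
    intergenic_gap: tuple[int, int] = (300, 900)
    uncharacterized_fraction: float = 0.1
    # RRHP counts
    tissues: tuple[str, ...] = ("muscle", "liver", "pituitary")
    n_replicates: int = 5
    capture_rate: float = 0.75
    baseline_log2_mean: float = math.log2(50.0)
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.1
    planted_fraction: float = 0.10
    planted_logfc: float = 2.0
    planted_baseline_log2_mean: float = math.log2(50.0)
    library_size_factors: tuple[float, float] = (0.7, 1.3)
    # expression
    focal_tissue: str = "muscle"
    expression_log2_mean: float = 6.0
    expression_log2_sd: float = 1.5
    expression_dispersion: float = 0.1
    expression_coupling: dict = field(
        default_factory=lambda: {"promoter": -1.0, "first_exon": -1.0, "first_intron": -1.0}
    )

    def __post_init__(self) -> None:
        if not (0 < self.capture_rate <= 1):
            raise ValueError("capture_rate must lie in (0, 1]")
        if self.dispersion < 0 or self.expression_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if not (0 <= self.planted_fraction < 1):
            raise ValueError("planted_fraction must lie in [0, 1)")

    def samples(self) -> list[SampleInfo]:
        return [
            SampleInfo(f"{t[0].upper()}{r}", t, r)
            for t in self.tissues
            for r in range(1, self.n_replicates + 1)
        ]

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stage])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedStudy:
    genome: list[GenomeSequence]
    site_truth: list[CcggSite]
    annotation: GenomeAnnotation
    count_matrix: CountMatrix
    rrhp_truth: pd.DataFrame
    expression: pd.DataFrame
    expression_truth: pd.DataFrame
    config: SimulationConfig


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: mean mu, variance mu + dispersion * mu^2."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mu * dispersion))


def _background(rng: np.random.Generator, length: int) -> list[str]:
    seq = rng.choice(list("ACGT"), size=length)
    s = "".join(seq)
    # destroy any background CCGG; the replacement base (A) can never
    # re-create the motif, so one pass suffices, but verify anyway
    while True:
        chars = list(s)
        hits = [m.start() for m in _CCGG.finditer(s)]
        if not hits:
            return chars
        for h in hits:
            chars[h + 1] = "A"
        s = "".join(chars)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomeSequence], list[CcggSite]]:
    """Motif-free random background with CCGG planted at Poisson-spaced spots.

    Junctions cannot create extra occurrences (the motif starts CC and ends
    GG), so the returned truth list is exactly the genome's site catalogue.
    """
    rng = rng or config.stage_rng(_STAGE_GENOME)
    if config.ccgg_density > 0 and 1000.0 / config.ccgg_density <= 4.0:
        raise ValueError(
            f"ccgg_density {config.ccgg_density}/kb infeasible: mean motif "
            "spacing must exceed the 4 bp motif length"
        )
    genome: list[GenomeSequence] = []
    truth: list[CcggSite] = []
    for c in range(config.n_chroms):
        name = f"chr{c + 1:02d}"
        L = config.chrom_length
        chars = _background(rng, L)
        chosen: list[int] = []
        if config.ccgg_density > 0:
            # Poisson-spaced starts: exponential gaps on top of the 4 bp
            # motif footprint, so the marginal density matches the target
            mean_gap = 1000.0 / config.ccgg_density
            p = -4
            while True:
                p += 4 + int(round(rng.exponential(mean_gap - 4.0)))
                if p > L - 4:
                    break
                chosen.append(p)
        for p in chosen:
            chars[p : p + 4] = "CCGG"
        genome.append(GenomeSequence(name, "".join(chars)))
        for p in chosen:
            truth.append(CcggSite(name, p + 1, "+"))
            truth.append(CcggSite(name, p + 4, "-"))
    truth.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return genome, truth


def simulate_annotation(
    genome: Sequence[GenomeSequence],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenomeAnnotation:
    """Non-overlapping genes with valid exon chains on random strands."""
    rng = rng or config.stage_rng(_STAGE_ANNOT)
    transcripts: list[TranscriptModel] = []
    gene_no = 0
    per_chrom = int(math.ceil(config.n_genes / max(len(genome), 1)))
    for rec in genome:
        cursor = 1
        placed = 0
        while placed < per_chrom and gene_no < config.n_genes:
            gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
            intron_lens = rng.integers(
                config.intron_length[0], config.intron_length[1] + 1, size=max(n_ex - 1, 0)
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursor + gap
            if start + span - 1 > rec.length:
                break
            exons: list[tuple[int, int]] = []
            pos = start
            for i in range(n_ex):
                exons.append((pos, pos + int(exon_lens[i]) - 1))
                pos += int(exon_lens[i])
                if i < n_ex - 1:
                    pos += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            desc = (
                f"uncharacterized LOC{900000 + gene_no}"
                if rng.random() < config.uncharacterized_fraction
                else f"protein coding gene {gene_no}"
            )
            if strand == "+":
                tss, tes = exons[0][0], exons[-1][1]
                ordered = exons
            else:
                tss, tes = exons[-1][1], exons[0][0]
                ordered = exons[::-1]
            transcripts.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    chrom=rec.name,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=ordered,
                    description=desc,
                )
            )
            cursor = start + span
            placed += 1
    if gene_no < config.n_genes:
        raise ValueError(
            f"could only place {gene_no}/{config.n_genes} genes; increase "
            "chrom_length/n_chroms or shrink gene geometry"
        )
    return GenomeAnnotation(transcripts=transcripts, parse_report={"n_transcripts": gene_no})


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Standard GFF3 with gene -> mRNA -> exon Parent chains."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(
            annotation.transcripts, key=lambda t: (t.chrom, min(t.span), t.gene_id)
        ):
            lo, hi = tx.span
            fh.write(
                f"{tx.chrom}\trrhp-sim\tgene\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.gene_id};description={tx.description}\n"
            )
            fh.write(
                f"{tx.chrom}\trrhp-sim\tmRNA\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(tx.exons), start=1):
                fh.write(
                    f"{tx.chrom}\trrhp-sim\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                )


def simulate_rrhp_counts(
    sites: Sequence[CcggSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Capture-dropout + lognormal baselines + planted effects + NB noise.

    Planted sites receive the configured |log2FC| in one designated tissue
    (tissues cycled, signs alternating) on a fixed baseline mean of
    ``2**planted_baseline_log2_mean``.  Truth rows: (chrom, position, strand,
    tissue, logfc, baseline_log2_mean).
    """
    if not sites:
        raise ValueError("no sites to simulate")
    rng = rng or config.stage_rng(_STAGE_COUNTS)
    samples = config.samples()
    n = len(sites)
    n_cap = max(1, int(round(config.capture_rate * n)))
    cap_idx = np.sort(rng.choice(n, size=n_cap, replace=False))
    captured = [sites[i] for i in cap_idx]
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_cap)
    n_planted = int(round(config.planted_fraction * n_cap))
    planted_idx = np.sort(rng.choice(n_cap, size=n_planted, replace=False))
    effect = np.zeros((n_cap, len(config.tissues)))
    truth_rows = []
    for j, i in enumerate(planted_idx):
        tissue = config.tissues[j % len(config.tissues)]
        sign = 1.0 if (j // len(config.tissues)) % 2 == 0 else -1.0
        lfc = sign * config.planted_logfc
        base[i] = config.planted_baseline_log2_mean
        effect[i, config.tissues.index(tissue)] = lfc
        s = captured[i]
        truth_rows.append(
            {"chrom": s.chrom, "position": s.position, "strand": s.strand,
             "tissue": tissue, "logfc": lfc,
             "baseline_log2_mean": config.planted_baseline_log2_mean}
        )
    lib = rng.uniform(*config.library_size_factors, size=len(samples))
    counts = np.zeros((n_cap, len(samples)), dtype=np.int64)
    for col, smp in enumerate(samples):
        t_idx = config.tissues.index(smp.tissue)
        mu = np.exp2(base + effect[:, t_idx]) * lib[col]
        counts[:, col] = _nb_draw(rng, mu, config.dispersion)
    keys = [(s.chrom, s.position, s.strand) for s in captured]
    df = pd.DataFrame(
        counts, index=pd.Index(keys, tupleize_cols=False),
        columns=[s.sample_id for s in samples],
    )
    observed = df.sum(axis=1) > 0
    df = df.loc[observed]
    matrix = CountMatrix(df, samples)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "position", "strand", "tissue", "logfc", "baseline_log2_mean"],
    )
    if len(truth):
        keep = [
            (r.chrom, r.position, r.strand) in set(df.index) for r in truth.itertuples()
        ]
        truth = truth.loc[keep].reset_index(drop=True)
    return matrix, truth


def matrix_to_read_starts(matrix: CountMatrix) -> dict[str, list]:
    """Expand each count cell into that many read-start records (no jitter)."""
    from .rrhp_counts import ReadStartRecord

    out: dict[str, list] = {s.sample_id: [] for s in matrix.samples}
    for key, row in matrix.counts.iterrows():
        chrom, pos, strand = key
        for sid, n in row.items():
            out[sid].extend([ReadStartRecord(chrom, pos, strand)] * int(n))
    return out


def gene_region_5hmc(
    focal_matrix: CountMatrix,
    annotations: Mapping[tuple, FeatureAnnotation],
    region_classes: Sequence[str] = ("promoter", "first_exon", "first_intron"),
) -> pd.DataFrame:
    """Per-gene max of mean focal-tissue counts within each region class."""
    from .expression_assoc import _region_mask

    mean_counts = focal_matrix.counts.mean(axis=1)
    data: dict[str, dict[str, float]] = {rc: {} for rc in region_classes}
    for key in focal_matrix.counts.index:
        ann = annotations[tuple(key)]
        if ann.gene_id is None:
            continue
        for rc in region_classes:
            if _region_mask(ann, rc):
                cur = data[rc].get(ann.gene_id, -np.inf)
                data[rc][ann.gene_id] = max(cur, float(mean_counts.loc[[key]].iloc[0]))
    return pd.DataFrame(data)


def simulate_expression(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    gene_5hmc: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB gene counts for the focal tissue's replicates, optionally coupled.

    Coupled genes have their log2 mean shifted by
    ``coupling[region_class] * z(log2(1 + region 5hmC))`` summed over the
    region classes in which they carry a 5hmC site.
    """
    rng = rng or config.stage_rng(_STAGE_EXPR)
    genes = sorted({tx.gene_id for tx in annotation.transcripts})
    if not genes:
        raise ValueError("annotation has no genes")
    base = rng.normal(config.expression_log2_mean, config.expression_log2_sd, size=len(genes))
    shift = np.zeros(len(genes))
    coupled = np.zeros(len(genes), dtype=bool)
    if gene_5hmc is not None:
        for rc, coef in config.expression_coupling.items():
            if coef == 0 or rc not in gene_5hmc.columns:
                continue
            col = np.log2(1.0 + gene_5hmc[rc].dropna())
            if len(col) < 2 or float(col.std(ddof=0)) == 0:
                continue
            z = (col - col.mean()) / col.std(ddof=0)
            for gid, zval in z.items():
                if gid in genes:
                    gi = genes.index(gid)
                    shift[gi] += coef * float(zval)
                    coupled[gi] = True
    sample_ids = [f"E{r}" for r in range(1, config.n_replicates + 1)]
    lib = rng.uniform(*config.library_size_factors, size=len(sample_ids))
    counts = np.zeros((len(genes), len(sample_ids)), dtype=np.int64)
    mu0 = np.exp2(base + shift)
    for col in range(len(sample_ids)):
        counts[:, col] = _nb_draw(rng, mu0 * lib[col], config.expression_dispersion)
    expr = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "base_log2_mean": base,
            "coupling_shift": shift,
            "coupled": coupled,
        }
    )
    return expr, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all generator stages in their fixed order under one seed."""
    genome, site_truth = simulate_genome(config)
    annotation = simulate_annotation(genome, config)
    matrix, rrhp_truth = simulate_rrhp_counts(site_truth, config)
    ann_map = annotate_sites([CcggSite(*k) for k in matrix.counts.index], annotation)
    focal = matrix.subset_tissue(config.focal_tissue)
    g5 = gene_region_5hmc(focal, ann_map)
    expression, expr_truth = simulate_expression(annotation, config, g5)
    return SimulatedStudy(
        genome=genome,
        site_truth=site_truth,
        annotation=annotation,
        count_matrix=matrix,
        rrhp_truth=rrhp_truth,
        expression=expression,
        expression_truth=expr_truth,
        config=config,
    )


def simulate_association_table(
    n_genes: int,
    coupling: float,
    rng: np.random.Generator,
    region_class: str = "promoter",
) -> tuple[pd.DataFrame, dict[tuple, FeatureAnnotation]]:
    """Gene-level association sampler: one region-class site per gene.

    Mean 5hmC is lognormal around ~50 counts; expression is normal on the
    log2 scale, shifted by ``coupling * z(log2 5hmC)``.  Used for fast
    calibration/power studies of the association machinery.
    """
    log2_hmc = rng.normal(math.log2(50.0), 1.0, size=n_genes)
    mean_5hmc = np.exp2(log2_hmc)
    z = (log2_hmc - log2_hmc.mean()) / log2_hmc.std(ddof=0)
    expression = rng.normal(8.0, 2.0, size=n_genes) + coupling * z
    rows = []
    annotations: dict[tuple, FeatureAnnotation] = {}
    if region_class == "promoter":
        feature, idx = "promoter", None
    elif region_class == "first_exon":
        feature, idx = "exon", (1, 3)
    elif region_class == "first_intron":
        feature, idx = "intron", (1, 2)
    else:
        raise ValueError(f"unknown region class {region_class!r}")
    for i in range(n_genes):
        site = CcggSite("chr01", 10 * (i + 1), "+")
        gid = f"gene{i + 1:04d}"
        dist = int(rng.integers(-900, 1500))
        annotations[tuple(site)] = FeatureAnnotation(site, feature, idx, gid, dist)
        rows.append(
            {
                "chrom": site.chrom, "position": site.position, "strand": site.strand,
                "mean_5hmc": float(mean_5hmc[i]), "tss_distance": dist,
                "gene_id": gid, "expression": float(expression[i]),
            }
        )
    table = pd.DataFrame(rows)
    table.index = pd.Index(
        [(r["chrom"], r["position"], r["strand"]) for r in rows], tupleize_cols=False
    )
    return table, annotations


def score_detection(
    results_by_contrast: Mapping[str, pd.DataFrame],
    contrast_pairs: Mapping[str, tuple[str, str]],
    truth: pd.DataFrame,
    q_threshold: float = 0.05,
) -> dict:
    """Sensitivity, false-discovery proportion and logFC error vs truth.

    A planted site is *recovered* when called (q < threshold) in at least one
    contrast involving its planted tissue; a call in a contrast whose tissue
    pair does not include the planted tissue (or at an unplanted site) is a
    false discovery for that contrast.
    """
    planted: dict[tuple, tuple[str, float]] = {
        (r.chrom, r.position, r.strand): (r.tissue, r.logfc) for r in truth.itertuples()
    }
    n_calls = 0
    n_false = 0
    recovered: set = set()
    errors: list[float] = []
    for name, res in results_by_contrast.items():
        t1, t2 = contrast_pairs[name]
        called = res[res["q"] < q_threshold]
        n_calls += len(called)
        for key in called.index:
            info = planted.get(tuple(key))
            if info is None or info[0] not in (t1, t2):
                n_false += 1
            else:
                recovered.add(tuple(key))
        for key, (tissue, lfc) in planted.items():
            if tissue not in (t1, t2) or tuple(key) not in res.index:
                continue
            expected = lfc if tissue == t1 else -lfc
            errors.append(float(res.loc[[tuple(key)]]["logFC"].iloc[0]) - expected)
    n_true = len(planted)
    return {
        "n_planted": n_true,
        "n_calls": n_calls,
        "sensitivity": len(recovered) / n_true if n_true else float("nan"),
        "fdp": n_false / n_calls if n_calls else 0.0,
        "mean_logfc_error": float(np.mean(errors)) if errors else float("nan"),
        "mean_abs_logfc_error": float(np.mean(np.abs(errors))) if errors else float("nan"),
    }
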