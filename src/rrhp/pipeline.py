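"""File-to-file pipeline stages and the end-to-end orchestrator.

Every stage reads and writes the plain-text interchange formats of its
module (TSV with a one-line header, JSON for nested summaries), so chaining
the CLI subcommands by hand produces byte-identical outputs to ``run_all``.
All thresholds are configuration with the study's values as defaults; nothing
is hard-coded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import differential as diff_mod
from . import expression_assoc as assoc_mod
from . import genome_io, rrhp_counts, synthetic_data

__all__ = [
    "default_config",
    "load_config",
    "run_all",
    "stage_simulate",
    "stage_catalog",
    "stage_count",
    "stage_filter",
    "stage_diff",
    "stage_annotate",
    "stage_enrich",
    "stage_associate",
]


def default_config(seed: int = 0, outdir: str = "rrhp_out") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {},  # SimulationConfig overrides; section present => simulate inputs
        "filter": {
            "group_threshold": 1,
            "min_failing_groups": 2,
            "group_stat": "sum",
            "median_override": None,
            "median_rule": "per_tissue_all",
            "sample_quorum": 5,
        },
        "differential": {
            "prior_count": 0.5,
            "q_thresholds": dict(diff_mod.DEFAULT_Q_THRESHOLDS),
            "default_q_threshold": 0.05,
        },
        "annotation": {
            "promoter_window": list(ann_mod.PROMOTER_WINDOW),
            "tts_window": list(ann_mod.TTS_WINDOW),
            "exclude_description_pattern": "uncharacterized",
        },
        "association": {
            "focal_tissue": "muscle",
            "log_5hmc": False,
            "abs_distance": False,
            "gene_agg": "max",
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = synthetic_data.SimulationConfig(
        seed=int(config.get("seed", 0)), **config.get("simulate", {})
    )
    study = synthetic_data.simulate_study(sim_cfg)
    genome_io.write_fasta(study.genome, outdir / "genome.fa")
    synthetic_data.write_gff3(study.annotation, outdir / "annotation.gff3")
    rs_dir = outdir / "read_starts"
    rs_dir.mkdir(exist_ok=True)
    records = synthetic_data.matrix_to_read_starts(study.count_matrix)
    paths = {}
    for sid, recs in records.items():
        p = rs_dir / f"{sid}.tsv"
        rrhp_counts.write_read_starts(recs, p)
        paths[sid] = str(p)
    rrhp_counts.write_sample_sheet(study.count_matrix.samples, outdir / "sample_sheet.tsv", paths)
    rrhp_counts.write_count_matrix_tsv(study.count_matrix, outdir / "true_counts.tsv")
    study.rrhp_truth.to_csv(outdir / "rrhp_truth.tsv", sep="\t", index=False)
    expr = study.expression.copy()
    expr.insert(0, "gene_id", expr.index)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    study.expression_truth.to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)
    genome_io.write_site_catalog_tsv(study.site_truth, outdir / "site_truth.tsv")
    return {
        "genome": str(outdir / "genome.fa"),
        "gff3": str(outdir / "annotation.gff3"),
        "sample_sheet": str(outdir / "sample_sheet.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "n_sites_simulated": len(study.site_truth),
        "n_sites_captured": study.count_matrix.n_sites,
    }


def stage_catalog(genome_path: str, outdir: Path, chrom_subset=None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = genome_io.read_fasta(genome_path)
    sites = genome_io.catalog_ccgg_sites(genome, chrom_subset=chrom_subset)
    genome_io.write_site_catalog_tsv(sites, outdir / "catalog.tsv")
    genome_io.write_site_catalog_bed(sites, outdir / "catalog.bed")
    return {"catalog": str(outdir / "catalog.tsv"), "n_catalog_sites": len(sites)}


def stage_count(sample_sheet: str, outdir: Path, catalog_tsv: str | None = None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    samples, paths = rrhp_counts.read_sample_sheet(sample_sheet)
    missing = [s.sample_id for s in samples if s.sample_id not in paths]
    if missing:
        raise ValueError(f"sample sheet lacks read-start paths for: {missing}")
    records = {sid: rrhp_counts.parse_read_starts(p) for sid, p in paths.items()}
    catalog = genome_io.read_site_catalog_tsv(catalog_tsv) if catalog_tsv else None
    matrix, report = rrhp_counts.build_count_matrix(records, samples, catalog=catalog)
    rrhp_counts.write_count_matrix_tsv(matrix, outdir / "counts.tsv")
    _write_json(report, outdir / "count_report.json")
    return {"counts": str(outdir / "counts.tsv"), **report}


def stage_filter(counts_tsv: str, sample_sheet: str, config: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    samples, _ = rrhp_counts.read_sample_sheet(sample_sheet)
    matrix = rrhp_counts.read_count_matrix_tsv(counts_tsv, samples)
    opts = config["filter"]
    filtered, report = rrhp_counts.apply_two_stage_filter(
        matrix,
        group_threshold=opts["group_threshold"],
        min_failing_groups=opts["min_failing_groups"],
        group_stat=opts["group_stat"],
        median_override=opts["median_override"],
        median_rule=opts["median_rule"],
        sample_quorum=opts["sample_quorum"],
    )
    rrhp_counts.write_count_matrix_tsv(filtered, outdir / "filtered_counts.tsv")
    report.to_json(outdir / "filter_report.json")
    return {
        "filtered_counts": str(outdir / "filtered_counts.tsv"),
        "n_retained": report.n_retained,
        "n_removed_group_filter": report.n_removed_group_filter,
        "n_removed_median_filter": report.n_removed_median_filter,
        "global_median": report.global_median,
    }


def _q_threshold(config: dict, name: str) -> float:
    dd = config["differential"]
    return float(dd["q_thresholds"].get(name, dd["default_q_threshold"]))


def stage_diff(filtered_tsv: str, sample_sheet: str, config: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    samples, _ = rrhp_counts.read_sample_sheet(sample_sheet)
    matrix = rrhp_counts.read_count_matrix_tsv(filtered_tsv, samples)
    results, prior = diff_mod.run_differential(
        matrix, prior_count=config["differential"]["prior_count"]
    )
    call_counts = {}
    call_paths = {}
    for name, res in results.items():
        diff_mod.write_differential_tsv(res, outdir / f"diff_{name}.tsv")
        calls = diff_mod.call_dhmc(res, _q_threshold(config, name))
        diff_mod.write_differential_tsv(calls, outdir / f"calls_{name}.tsv")
        call_counts[name] = int(len(calls))
        call_paths[name] = str(outdir / f"calls_{name}.tsv")
    called_sets = {
        name: set(diff_mod.call_dhmc(res, _q_threshold(config, name)).index)
        for name, res in results.items()
    }
    inter = set.intersection(*called_sets.values()) if called_sets else set()
    summary = {
        "d0": prior.d0,
        "s0_sq": prior.s0_sq,
        "calls_per_contrast": call_counts,
        "n_sites_called_in_all_contrasts": len(inter),
        "q_thresholds": {n: _q_threshold(config, n) for n in results},
    }
    _write_json(summary, outdir / "diff_summary.json")
    return {"contrasts": sorted(results), "call_paths": call_paths, **summary}


def _read_annotation_tsv(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"feature_index": str})
    out = {}
    for r in df.itertuples():
        idx = None
        if r.feature_index:
            k, n = r.feature_index.split("/")
            idx = (int(k), int(n))
        site = genome_io.CcggSite(str(r.chrom), int(r.position), str(r.strand))
        out[tuple(site)] = ann_mod.FeatureAnnotation(
            site,
            r.feature,
            idx,
            r.gene_id if r.gene_id != "" else None,
            int(r.tss_distance) if r.tss_distance != "" else None,
            r.gene_description,
        )
    return out


def stage_annotate(gff3: str, filtered_tsv: str, sample_sheet: str, config: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = genome_io.read_gff3(gff3)
    samples, _ = rrhp_counts.read_sample_sheet(sample_sheet)
    matrix = rrhp_counts.read_count_matrix_tsv(filtered_tsv, samples)
    opts = config["annotation"]
    ann_map = ann_mod.annotate_sites(
        [genome_io.CcggSite(*k) for k in matrix.counts.index],
        annotation,
        promoter_window=tuple(opts["promoter_window"]),
        tts_window=tuple(opts["tts_window"]),
    )
    ann_mod.annotations_frame(ann_map).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    return {"annotation": str(outdir / "annotation.tsv"), "n_annotated": len(ann_map)}


def _read_calls(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.index = pd.Index(
        [(r.chrom, int(r.position), r.strand) for r in df.itertuples()], tupleize_cols=False
    )
    return df


def stage_enrich(
    call_paths: dict[str, str],
    annotation_tsv: str,
    filtered_tsv: str,
    sample_sheet: str,
    config: dict,
    outdir: Path,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    ann_map = _read_annotation_tsv(annotation_tsv)
    samples, _ = rrhp_counts.read_sample_sheet(sample_sheet)
    matrix = rrhp_counts.read_count_matrix_tsv(filtered_tsv, samples)
    calls_by_contrast = {name: _read_calls(p) for name, p in sorted(call_paths.items())}

    enrich_rows = []
    for name, calls in calls_by_contrast.items():
        for e in ann_mod.feature_enrichment(calls, ann_map, name):
            enrich_rows.append(vars(e))
    pd.DataFrame(
        enrich_rows,
        columns=["contrast", "feature", "n_hyper_in", "n_hyper_out", "n_hypo_in",
                 "n_hypo_out", "odds_ratio", "p", "tier"],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    union = sorted(set().union(*(set(c.index) for c in calls_by_contrast.values())) if calls_by_contrast else set())
    if union:
        y = diff_mod.log_cpm(matrix, prior_count=config["differential"]["prior_count"])
        tissue_means = pd.DataFrame(
            {t: y[matrix.columns_for(t)].mean(axis=1) for t in matrix.tissues}
        ).loc[union]
        rel, rel_report = ann_mod.relative_feature_enrichment(
            tissue_means, {k: ann_map[k].feature for k in union}
        )
        rel_rows = [vars(r) for r in rel]
    else:
        rel_rows, rel_report = [], {"n_ties_excluded": 0, "tissues_without_topped_sites": []}
    pd.DataFrame(
        rel_rows,
        columns=["tissue", "feature", "proportion_in_tissue",
                 "mean_proportion_other_tissues", "relative_enrichment_pct"],
    ).to_csv(outdir / "relative_enrichment.tsv", sep="\t", index=False)

    sets = ann_mod.gene_level_sets(
        calls_by_contrast, ann_map,
        exclude_description_pattern=config["annotation"]["exclude_description_pattern"],
    )
    gs_dir = outdir / "gene_sets"
    gs_dir.mkdir(exist_ok=True)
    set_sizes = {}
    for name, d in sets["per_contrast"].items():
        for direction in ("hyper", "hypo", "both"):
            genes = sorted(d[direction])
            (gs_dir / f"{name}_{direction}.txt").write_text("".join(g + "\n" for g in genes))
            set_sizes[f"{name}_{direction}"] = len(genes)
    summary = {
        "gene_set_sizes": set_sizes,
        "pairwise_hyper_intersections": {
            k: len(v) for k, v in sets["pairwise_hyper_intersections"].items()
        },
        "n_excluded_uncharacterized": sets["n_excluded_uncharacterized"],
        "relative_enrichment_report": rel_report,
    }
    _write_json(summary, outdir / "enrich_summary.json")
    return summary


def stage_associate(
    filtered_tsv: str,
    sample_sheet: str,
    annotation_tsv: str,
    expression_tsv: str,
    config: dict,
    outdir: Path,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    samples, _ = rrhp_counts.read_sample_sheet(sample_sheet)
    matrix = rrhp_counts.read_count_matrix_tsv(filtered_tsv, samples)
    ann_map = _read_annotation_tsv(annotation_tsv)
    opts = config["association"]
    focal = matrix.subset_tissue(opts["focal_tissue"])

    expr_df = pd.read_csv(expression_tsv, sep="\t").set_index("gene_id")
    factors = assoc_mod.size_factors(expr_df)
    expression = assoc_mod.normalized_expression(expr_df, factors)

    table, join_report = assoc_mod.build_association_table(focal, ann_map, expression)
    table.to_csv(outdir / "association.tsv", sep="\t", index=False)

    summary: dict = {"association": join_report}
    if len(table) >= 3:
        try:
            pca = assoc_mod.pca3(
                table, log_5hmc=opts["log_5hmc"], abs_distance=opts["abs_distance"]
            )
            _write_json(pca.to_dict(), outdir / "pca.json")
            summary["pca_explained"] = pca.explained.tolist()
        except ValueError as exc:
            summary["pca_skipped"] = str(exc)
        corr = {}
        for a, b in (("mean_5hmc", "expression"), ("mean_5hmc", "tss_distance"),
                     ("tss_distance", "expression")):
            try:
                rho, p = assoc_mod.spearman(table[a], table[b])
                corr[f"{a}~{b}"] = {"rho": rho, "p": p}
            except ValueError as exc:
                corr[f"{a}~{b}"] = {"error": str(exc)}
        summary["spearman"] = corr
        _write_json(corr, outdir / "spearman.json")

    ks_rows = []
    for rc in assoc_mod.REGION_CLASSES:
        try:
            r = assoc_mod.high_low_5hmc_comparison(table, ann_map, rc, gene_agg=opts["gene_agg"])
            ks_rows.append(
                {"region_class": rc, "D": r.d, "p": r.p, "n_high": r.n_high, "n_low": r.n_low,
                 "quartiles_high": ";".join(f"{q:.6g}" for q in r.quartiles_high),
                 "quartiles_low": ";".join(f"{q:.6g}" for q in r.quartiles_low),
                 "note": ""}
            )
        except ValueError as exc:
            ks_rows.append({"region_class": rc, "D": "", "p": "", "n_high": 0, "n_low": 0,
                            "quartiles_high": "", "quartiles_low": "", "note": str(exc)})
    pd.DataFrame(
        ks_rows,
        columns=["region_class", "D", "p", "n_high", "n_low",
                 "quartiles_high", "quartiles_low", "note"],
    ).to_csv(outdir / "ks.tsv", sep="\t", index=False)
    summary["ks"] = {
        r["region_class"]: (r["p"] if r["p"] != "" else None) for r in ks_rows
    }
    return summary


# ---------------------------------------------------------------------------
# orchestrator


def run_all(config: dict) -> dict:
    """catalog -> count -> filter -> diff -> annotate -> enrich -> associate.

    When the config has a ``simulate`` section (always present in the default
    config), synthetic inputs are generated first.  Writes every intermediate
    plus ``summary.json``; deterministic given the config and seed.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.get("seed", 0)}

    inputs = dict(config.get("inputs", {}))
    if "simulate" in config and config["simulate"] is not None and not inputs:
        sim = stage_simulate(config, outdir)
        inputs = {k: sim[k] for k in ("genome", "gff3", "sample_sheet", "expression")}
        summary["simulate"] = {
            "n_sites_simulated": sim["n_sites_simulated"],
            "n_sites_captured": sim["n_sites_captured"],
        }
    for key in ("genome", "gff3", "sample_sheet"):
        if key not in inputs:
            raise ValueError(f"run_all: missing input {key!r}")

    cat = stage_catalog(inputs["genome"], outdir)
    summary["n_catalog_sites"] = cat["n_catalog_sites"]

    cnt = stage_count(inputs["sample_sheet"], outdir, catalog_tsv=cat["catalog"])
    summary["n_count_sites"] = cnt["n_sites"]

    flt = stage_filter(cnt["counts"], inputs["sample_sheet"], config, outdir)
    summary["filter"] = {k: flt[k] for k in
                         ("n_retained", "n_removed_group_filter",
                          "n_removed_median_filter", "global_median")}

    dif = stage_diff(flt["filtered_counts"], inputs["sample_sheet"], config, outdir)
    summary["differential"] = {
        "d0": dif["d0"], "s0_sq": dif["s0_sq"],
        "calls_per_contrast": dif["calls_per_contrast"],
        "n_sites_called_in_all_contrasts": dif["n_sites_called_in_all_contrasts"],
    }

    annr = stage_annotate(inputs["gff3"], flt["filtered_counts"], inputs["sample_sheet"], config, outdir)
    summary["n_annotated"] = annr["n_annotated"]

    enr = stage_enrich(dif["call_paths"], annr["annotation"], flt["filtered_counts"],
                       inputs["sample_sheet"], config, outdir)
    summary["enrichment"] = {
        "gene_set_sizes": enr["gene_set_sizes"],
        "pairwise_hyper_intersections": enr["pairwise_hyper_intersections"],
    }

    if "expression" in inputs:
        assoc = stage_associate(flt["filtered_counts"], inputs["sample_sheet"],
                                annr["annotation"], inputs["expression"], config, outdir)
        summary["association"] = assoc

    _write_json({"config": config, **summary}, outdir / "summary.json")
    return summary
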