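"""Expression normalization, PCA, Spearman/KS statistics and median splits."""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from rrhp.annotation import FeatureAnnotation
from rrhp.expression_assoc import (
    REGION_CLASSES,
    build_association_table,
    high_low_5hmc_comparison,
    ks_two_sample,
    normalized_expression,
    pca3,
    size_factors,
    spearman,
)
from rrhp.genome_io import CcggSite


def median_of_ratios_oracle(counts: pd.DataFrame) -> np.ndarray:
    """Literal definition: per-sample median of count / gene geometric mean."""
    factors = []
    genes = [g for g in counts.index if (counts.loc[g] > 0).all()]
    geo = {g: math.exp(sum(math.log(c) for c in counts.loc[g]) / counts.shape[1])
           for g in genes}
    for col in counts.columns:
        ratios = sorted(counts.loc[g, col] / geo[g] for g in genes)
        n = len(ratios)
        med = ratios[n // 2] if n % 2 else (ratios[n // 2 - 1] + ratios[n // 2]) / 2
        factors.append(med)
    return np.array(factors)


def mid_ranks(values: np.ndarray) -> np.ndarray:
    """Average-of-positions ranks computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = np.empty(len(values))
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ks_exact_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """D as the ECDF sup-difference; exact p by lattice-path counting.

    Valid for tie-free samples: count monotone lattice paths from (0,0) to
    (n,m) whose deviation |i*m - j*n| stays strictly below the observed
    integer statistic; p = 1 - that fraction.
    """
    n, m = len(a), len(b)
    pooled = sorted(set(a) | set(b))
    d = max(
        abs((a <= x).sum() / n - (b <= x).sum() / m) for x in pooled
    )
    t_obs = round(d * n * m)
    ways = np.zeros((n + 1, m + 1), dtype=object)
    ways[0][0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if i == j == 0:
                continue
            if abs(i * m - j * n) >= t_obs:
                ways[i][j] = 0
                continue
            ways[i][j] = (ways[i - 1][j] if i else 0) + (ways[i][j - 1] if j else 0)
    p = 1.0 - ways[n][m] / comb(n + m, n)
    return d, p


class TestSizeFactors:
    def test_matches_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"E{i}" for i in range(6)],
        )
        counts.iloc[0, 0] = 0  # one gene excluded from the reference
        sf = size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), median_of_ratios_oracle(counts))
        assert sf.attrs["fallback"] is False

    def test_scaling_a_sample_scales_its_factor(self, rng):
        counts = pd.DataFrame(
            rng.integers(10, 500, size=(100, 4)),
            index=[f"g{i}" for i in range(100)],
            columns=list("ABCD"),
        )
        doubled = counts.copy()
        doubled["B"] = counts["B"] * 2
        sf0, sf1 = size_factors(counts), size_factors(doubled)
        # factors are defined up to a common scale; the B:A ratio must double
        ratio0 = sf0["B"] / sf0["A"]
        ratio1 = sf1["B"] / sf1["A"]
        assert ratio1 / ratio0 == pytest.approx(2.0, rel=1e-9)

    def test_fallback_when_every_gene_has_a_zero(self):
        counts = pd.DataFrame({"A": [0, 4], "B": [6, 0]}, index=["g1", "g2"])
        sf = size_factors(counts)
        assert sf.attrs["fallback"] is True
        # column-sum ratios normalized to geometric mean 1
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
        assert sf["B"] / sf["A"] == pytest.approx(6.0 / 4.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            size_factors(pd.DataFrame({"A": [-1]}))


class TestNormalizedExpression:
    def test_formula_direct(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 300, size=(20, 3)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=list("ABC"),
        )
        sf = pd.Series([0.5, 1.0, 2.0], index=list("ABC"))
        expr = normalized_expression(counts, sf)
        for g in counts.index:
            expected = np.mean([math.log2(counts.loc[g, c] / sf[c] + 1.0) for c in "ABC"])
            assert expr[g] == pytest.approx(expected)

    def test_nonpositive_factor_rejected(self):
        counts = pd.DataFrame({"A": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="positive"):
            normalized_expression(counts, pd.Series({"A": 0.0}))


def make_table(rng, n=200, coupled=True):
    hmc = rng.gamma(3.0, 20.0, size=n)
    dist = rng.integers(-900, 100, size=n)
    noise = rng.normal(0, 1.0, size=n)
    expr = 8.0 - (1.2 if coupled else 0.0) * (np.log2(hmc + 1) - np.log2(hmc + 1).mean()) + noise
    keys = [("c1", int(i * 10 + 1), "+") for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": "c1",
            "position": [k[1] for k in keys],
            "strand": "+",
            "mean_5hmc": hmc,
            "tss_distance": dist,
            "gene_id": [f"g{i}" for i in range(n)],
            "expression": expr,
        },
        index=pd.Index(keys, tupleize_cols=False),
    )


class TestPca3:
    def test_eigen_structure(self, rng):
        res = pca3(make_table(rng))
        assert res.eigenvalues.sum() == pytest.approx(3.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.explained.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(res.cos2.sum(axis=1).to_numpy(), np.ones(3), rtol=1e-9)

    def test_loadings_are_variable_component_correlations(self, rng):
        table = make_table(rng)
        res = pca3(table)
        data = table[["mean_5hmc", "tss_distance", "expression"]].astype(float)
        z = (data - data.mean()) / data.std(ddof=0)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        scores = z.to_numpy() @ eigvec  # component scores, any sign
        for ci in range(3):
            for vi, var in enumerate(["mean_5hmc", "tss_distance", "expression"]):
                r = np.corrcoef(z.to_numpy()[:, vi], scores[:, 2 - ci])[0, 1]
                assert abs(res.loadings.iloc[vi, ci]) == pytest.approx(abs(r), abs=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = pca3(make_table(rng))
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_coupled_data_puts_5hmc_and_expression_on_pc1_opposed(self, rng):
        res = pca3(make_table(rng, n=2000, coupled=True))
        l = res.loadings["PC1"]
        assert l["mean_5hmc"] * l["expression"] < 0
        assert res.explained[0] > 1.0 / 3.0

    def test_zero_variance_variable_rejected(self, rng):
        table = make_table(rng, n=10)
        table["expression"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            pca3(table)

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            pca3(make_table(rng, n=2))


class TestSpearman:
    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=50)
            y = rng.normal(size=50) + 0.5 * x
            rho, _ = spearman(x, y)
            rx, ry = mid_ranks(x), mid_ranks(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, rel=1e-12)

    def test_ties_use_mid_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 4.0, 9.0])
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(mid_ranks(x), mid_ranks(y))[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_perfect_monotone_is_one(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -np.sqrt(x + 1))
        assert rho == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKsTwoSample:
    def test_matches_lattice_path_oracle_small_samples(self, rng):
        for _ in range(5):
            a = rng.normal(size=int(rng.integers(4, 12)))
            b = rng.normal(loc=0.5, size=int(rng.integers(4, 12)))
            d, p = ks_two_sample(a, b)
            d_o, p_o = ks_exact_oracle(a, b)
            assert d == pytest.approx(d_o, rel=1e-12)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_identical_samples_d_zero(self):
        a = np.arange(5.0)
        d, p = ks_two_sample(a, a)
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_samples_d_one(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == 1.0
        # exact: only 1 of C(6,3)=20 interleavings reaches separation 1
        assert p == pytest.approx(2.0 / 20.0, rel=1e-9)

    def test_large_samples_use_asymptotic(self, rng):
        a = rng.normal(size=150)
        b = rng.normal(size=150)  # 150*150 > 10,000
        d, p = ks_two_sample(a, b)
        from scipy import stats
        res = stats.ks_2samp(a, b, method="asymp")
        assert (d, p) == (res.statistic, res.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_two_sample([], [1.0])


def _ann(key, feature, idx=None, gene="g1", dist=0):
    return FeatureAnnotation(CcggSite(*key), feature, idx, gene, dist)


class TestBuildAssociationTable:
    def test_join_and_drop_accounting(self, small_study):
        from rrhp.annotation import annotate_sites

        matrix = small_study.count_matrix.subset_tissue("muscle")
        anns = annotate_sites(matrix.sites, small_study.annotation)
        sf = size_factors(small_study.expression)
        expr = normalized_expression(small_study.expression, sf)
        table, report = build_association_table(matrix, anns, expr)
        assert report["n_records"] + report["n_dropped_no_expression"] == matrix.n_sites
        assert report["n_records"] == len(table)
        # spot-check the join on a few records
        for key in list(table.index)[:10]:
            assert table.loc[[key]]["gene_id"].iloc[0] == anns[key].gene_id
            assert table.loc[[key]]["expression"].iloc[0] == pytest.approx(
                float(expr[anns[key].gene_id])
            )
            assert table.loc[[key]]["mean_5hmc"].iloc[0] == pytest.approx(
                float(matrix.counts.loc[[key]].mean(axis=1).iloc[0])
            )


class TestHighLowComparison:
    def _table(self, levels_by_gene, expr_by_gene, feature="promoter", idx=None):
        keys, anns, rows = [], {}, []
        i = 0
        for gene, levels in levels_by_gene.items():
            for lv in levels:
                key = ("c1", i * 10 + 1, "+")
                keys.append(key)
                anns[key] = _ann(key, feature, idx, gene)
                rows.append({"chrom": "c1", "position": key[1], "strand": "+",
                             "mean_5hmc": lv, "tss_distance": 0, "gene_id": gene,
                             "expression": expr_by_gene[gene]})
                i += 1
        table = pd.DataFrame(rows, index=pd.Index(keys, tupleize_cols=False))
        return table, anns

    def test_gene_aggregation_is_max_and_median_ties_go_low(self):
        levels = {"g1": [1.0, 9.0], "g2": [8.0], "g3": [5.0], "g4": [5.0],
                  "g5": [2.0], "g6": [1.0]}
        expr = {g: float(i) for i, g in enumerate(levels)}
        table, anns = self._table(levels, expr)
        # with max aggregation g1 -> 9, levels (9,8,5,5,2,1), median 5,
        # genes at the median go low: high = {g1, g2}
        res = high_low_5hmc_comparison(table, anns, "promoter", gene_agg="max")
        assert (res.n_high, res.n_low) == (2, 4)
        # with mean aggregation g1 -> 5 joins the tie at the median and only
        # g2 remains high, which is below the 2-genes-per-group minimum
        with pytest.raises(ValueError, match=">= 2 genes"):
            high_low_5hmc_comparison(table, anns, "promoter", gene_agg="mean")

    def test_median_tie_assignment(self):
        levels = {"g1": [9.0], "g2": [8.0], "g3": [5.0], "g4": [5.0], "g5": [1.0], "g6": [2.0]}
        expr = {g: float(i) for i, g in enumerate(levels)}
        table, anns = self._table(levels, expr)
        res = high_low_5hmc_comparison(table, anns, "promoter")
        # median of (9,8,5,5,1,2) = 5; the two genes at 5 go low
        assert (res.n_high, res.n_low) == (2, 4)

    def test_region_class_filters_by_first_index(self):
        keys = [("c1", 1, "+"), ("c1", 11, "+"), ("c1", 21, "+"), ("c1", 31, "+"),
                ("c1", 41, "+"), ("c1", 51, "+")]
        anns = {
            keys[0]: _ann(keys[0], "exon", (1, 3), "g1"),
            keys[1]: _ann(keys[1], "exon", (2, 3), "g2"),   # not first exon
            keys[2]: _ann(keys[2], "exon", (1, 3), "g3"),
            keys[3]: _ann(keys[3], "exon", (1, 3), "g4"),
            keys[4]: _ann(keys[4], "exon", (1, 3), "g5"),
            keys[5]: _ann(keys[5], "promoter", None, "g6"),
        }
        rows = [{"chrom": "c1", "position": k[1], "strand": "+", "mean_5hmc": float(i),
                 "tss_distance": 0, "gene_id": f"g{i + 1}", "expression": float(i)}
                for i, k in enumerate(keys)]
        table = pd.DataFrame(rows, index=pd.Index(keys, tupleize_cols=False))
        res = high_low_5hmc_comparison(table, anns, "first_exon")
        assert res.n_high + res.n_low == 4  # g2 (2nd exon) and g6 (promoter) excluded

    def test_quartiles_reported(self):
        levels = {f"g{i}": [float(i)] for i in range(8)}
        expr = {f"g{i}": float(i) for i in range(8)}
        table, anns = self._table(levels, expr)
        res = high_low_5hmc_comparison(table, anns, "promoter")
        assert res.quartiles_high[0] >= res.quartiles_low[0]
        assert len(res.quartiles_high) == 5

    def test_unknown_region_class_rejected(self):
        table, anns = self._table({"g1": [1.0]}, {"g1": 1.0})
        with pytest.raises(ValueError, match="unknown region class"):
            high_low_5hmc_comparison(table, anns, "enhancer")

    def test_empty_region_rejected(self):
        table, anns = self._table({"g1": [1.0]}, {"g1": 1.0}, feature="TTS")
        with pytest.raises(ValueError, match="no sites"):
            high_low_5hmc_comparison(table, anns, "promoter")

    def test_too_few_genes_per_group_rejected(self):
        table, anns = self._table({"g1": [1.0], "g2": [2.0]}, {"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError, match=">= 2 genes"):
            high_low_5hmc_comparison(table, anns, "promoter")


class TestPlantedCouplingRecovered:
    def test_negative_promoter_association_in_coupled_study(self, assoc_study):
        from rrhp.annotation import annotate_sites

        matrix = assoc_study.count_matrix.subset_tissue("muscle")
        anns = annotate_sites(matrix.sites, assoc_study.annotation)
        sf = size_factors(assoc_study.expression)
        expr = normalized_expression(assoc_study.expression, sf)
        table, _ = build_association_table(matrix, anns, expr)
        res = high_low_5hmc_comparison(table, anns, "promoter")
        assert res.p < 0.01
        assert res.quartiles_high[2] < res.quartiles_low[2]  # median expression lower
        keep = [k for k in table.index if anns[k].feature == "promoter"]
        rho, p = spearman(
            np.log2(table.loc[keep, "mean_5hmc"] + 1.0), table.loc[keep, "expression"]
        )
        assert rho < 0 and p < 0.001
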