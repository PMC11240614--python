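"""Association engines, thresholds, ensembling, and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heterogen import (
    additive_grm,
    annotate_nearest_gene,
    bonferroni_thresholds,
    dominance_grm,
    ensemble_combine,
    scan_multi_locus,
    scan_single_locus,
)
from heterogen.gwas_scan import ScanResult, read_gff_genes
from heterogen.kinship import GRM

from conftest import make_panel


class TestThresholds:
    def test_small_panel_arithmetic(self):
        th = bonferroni_thresholds(100)
        assert th.significant == pytest.approx(5e-4)
        assert th.suggestive == pytest.approx(1e-2)

    def test_retained_panel_size_thresholds(self):
        th = bonferroni_thresholds(112_643)
        assert th.significant == pytest.approx(4.4388e-7, rel=1e-4)
        assert th.suggestive == pytest.approx(8.8776e-6, rel=1e-4)

    @pytest.mark.parametrize("n", [1, 7, 1000, 112_643])
    def test_suggestive_is_twenty_times_significant(self, n):
        th = bonferroni_thresholds(n)
        assert th.suggestive / th.significant == pytest.approx(20.0)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_thresholds(0)


class TestSingleLocusOracle:
    """P3D p-values vs explicit dense GLS, and the OLS reduction."""

    def _dense_gls_pvalues(self, y, X, M, V):
        Vi = np.linalg.inv(V)
        n = y.size
        pvals = np.empty(M.shape[1])
        for j in range(M.shape[1]):
            Xj = np.column_stack([X, M[:, j]])
            XtViX = Xj.T @ Vi @ Xj
            C = np.linalg.inv(XtViX)
            b = C @ Xj.T @ Vi @ y
            r = y - Xj @ b
            s2 = (r @ Vi @ r) / (n - Xj.shape[1])
            t = b[-1] / np.sqrt(s2 * C[-1, -1])
            pvals[j] = 2 * stats.t.sf(abs(t), n - Xj.shape[1])
        return pvals

    def test_p3d_matches_dense_gls(self):
        g, d = make_panel(40, 50, seed=50)
        Ga = additive_grm(d)
        rng = np.random.default_rng(51)
        y = d.Z[:, 3] * 0.5 + rng.standard_normal(40)
        scan = scan_single_locus(y, None, d, Ga, "additive")
        V = scan.null_sigma2_e * (scan.null_lambda * Ga.values + np.eye(40))
        expected = self._dense_gls_pvalues(y, np.ones((40, 1)), d.Z, V)
        assert np.allclose(scan.table["p"], expected, atol=1e-8)

    def test_identity_kinship_reduces_to_ols(self):
        import statsmodels.api as sm

        g, d = make_panel(40, 50, seed=52)
        eye = GRM(values=np.eye(40), kind="additive",
                  samples=[f"i{j}" for j in range(40)], denominator=1.0)
        rng = np.random.default_rng(53)
        y = rng.standard_normal(40)
        scan = scan_single_locus(y, None, d, eye, "additive")
        ols_p = np.array(
            [
                sm.OLS(y, sm.add_constant(d.Z[:, j])).fit().pvalues[1]
                for j in range(50)
            ]
        )
        assert np.allclose(scan.table["p"], ols_p, atol=1e-10)

    def test_exact_per_snp_estimation_agrees_with_p3d_under_null(self):
        g, d = make_panel(60, 20, seed=54)
        Ga = additive_grm(d)
        y = np.random.default_rng(55).standard_normal(60)
        fast = scan_single_locus(y, None, d, Ga, "additive", p3d=True)
        slow = scan_single_locus(y, None, d, Ga, "additive", p3d=False)
        # per-SNP refits move lambda only slightly under the null
        assert np.allclose(
            np.log10(fast.table["p"]), np.log10(slow.table["p"]), atol=0.2
        )


class TestSingleLocusBehavior:
    def test_planted_additive_qtn_is_top_hit(self):
        hits = 0
        for rep in range(10):
            g, d = make_panel(500, 300, seed=60 + rep)
            Ga = additive_grm(d)
            rng = np.random.default_rng(600 + rep)
            q = int(rng.integers(300))
            zq = d.Z[:, q]
            y = zq * np.sqrt(0.2 / np.var(zq)) + rng.standard_normal(500) * np.sqrt(0.8)
            scan = scan_single_locus(y, None, d, Ga, "additive")
            hits += int(scan.table["p"].idxmin() == q)
        assert hits >= 9

    def test_collinear_snp_gets_missing_pvalue(self):
        g, d = make_panel(30, 10, seed=64)
        Ga = additive_grm(d)
        d.Z[:, 4] = 0.0  # degenerate column, collinear with the intercept
        y = np.random.default_rng(65).standard_normal(30)
        with pytest.warns(UserWarning, match="collinear"):
            scan = scan_single_locus(y, None, d, Ga, "additive")
        assert np.isnan(scan.table["p"].iloc[4])
        assert scan.table["p"].iloc[:4].notna().all()

    def test_every_snp_reported_once(self):
        g, d = make_panel(100, 250, seed=66)
        Ga = additive_grm(d)
        y = np.random.default_rng(67).standard_normal(100)
        scan = scan_single_locus(y, None, d, Ga, "additive")
        assert len(scan.table) == 250
        assert scan.table["snp"].is_unique


class TestMultiLocus:
    def test_zero_cofactors_reduces_to_single_locus(self):
        g, d = make_panel(120, 200, seed=70)
        Ga = additive_grm(d)
        rng = np.random.default_rng(71)
        y = d.Z[:, 5] * 0.7 + rng.standard_normal(120)
        single = scan_single_locus(y, None, d, Ga, "additive")
        multi = scan_multi_locus(y, None, d, Ga, "additive", max_cofactors=0)
        assert np.allclose(multi.table["p"], single.table["p"], equal_nan=True)
        assert multi.cofactors == []

    def test_two_planted_qtns_both_selected(self):
        both = 0
        for rep in range(10):
            g, d = make_panel(500, 400, seed=80 + rep)
            Ga = additive_grm(d)
            rng = np.random.default_rng(800 + rep)
            q1, q2 = 37, 305  # far apart: linkage equilibrium
            z1, z2 = d.Z[:, q1], d.Z[:, q2]
            y = (
                z1 * np.sqrt(0.15 / np.var(z1))
                + z2 * np.sqrt(0.15 / np.var(z2))
                + rng.standard_normal(500) * np.sqrt(0.7)
            )
            scan = scan_multi_locus(y, None, d, Ga, "additive", max_cofactors=5)
            ids = {d.snps["id"].iloc[q1], d.snps["id"].iloc[q2]}
            both += int(ids <= set(scan.cofactors))
        assert both >= 8

    def test_null_data_selects_no_cofactors(self):
        none = 0
        for rep in range(10):
            g, d = make_panel(300, 400, seed=90 + rep)
            Ga = additive_grm(d)
            y = np.random.default_rng(900 + rep).standard_normal(300)
            scan = scan_multi_locus(y, None, d, Ga, "additive", max_cofactors=5)
            none += int(len(scan.cofactors) == 0)
        assert none >= 9


def _fake_scan(ids, pvals, engine, coding="additive"):
    table = pd.DataFrame(
        {
            "snp": ids,
            "chrom": "1",
            "pos": np.arange(1, len(ids) + 1) * 100,
            "coding": coding,
            "beta": 0.1,
            "se": 0.05,
            "p": pvals,
        }
    )
    return ScanResult(table=table, engine=engine, coding=coding)


class TestEnsemble:
    def test_snp_supported_by_both_engines_included(self):
        th = bonferroni_thresholds(100)
        a = _fake_scan(["s1", "s2"], [1e-4, 0.5], "mlm")
        b = _fake_scan(["s1", "s2"], [5e-3, 0.4], "mlmm")
        ens = ensemble_combine([a, b], th, min_support=2, tier="suggestive")
        assert ens.table["snp"].tolist() == ["s1"]
        assert ens.table["engines"].iloc[0] == "mlm,mlmm"
        assert ens.table["best_p"].iloc[0] == pytest.approx(1e-4)

    def test_single_engine_support_excluded(self):
        th = bonferroni_thresholds(100)
        a = _fake_scan(["s1"], [1e-6], "mlm")
        b = _fake_scan(["s1"], [0.9], "mlmm")
        ens = ensemble_combine([a, b], th, min_support=2)
        assert ens.table.empty

    def test_empty_scan_list_is_an_error(self):
        with pytest.raises(ValueError, match="at least one"):
            ensemble_combine([], bonferroni_thresholds(10))

    def test_mismatched_panels_rejected(self):
        th = bonferroni_thresholds(10)
        a = _fake_scan(["s1", "s2"], [0.1, 0.2], "mlm")
        b = _fake_scan(["s1", "s3"], [0.1, 0.2], "mlmm")
        with pytest.raises(ValueError, match="panel"):
            ensemble_combine([a, b], th)

    def test_tier_label_reflects_significant_support(self):
        th = bonferroni_thresholds(100)  # significant 5e-4, suggestive 1e-2
        a = _fake_scan(["s1"], [1e-5], "mlm")
        b = _fake_scan(["s1"], [1e-5], "mlmm")
        ens = ensemble_combine([a, b], th, min_support=2, tier="suggestive")
        assert ens.table["tier"].iloc[0] == "significant"


TOY_GFF = """##gff-version 3
1\ttoy\tgene\t1000\t2000\t.\t+\t.\tID=gene:G1;Name=GENE1
1\ttoy\tgene\t5000\t6000\t.\t-\t.\tID=gene:G2;Name=GENE2
2\ttoy\tgene\t300\t400\t.\t+\t.\tID=gene:G3;Name=GENE3
2\ttoy\tgene\t600\t700\t.\t+\t.\tID=gene:G4;Name=GENE4
"""


class TestAnnotation:
    @pytest.fixture
    def genes(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(TOY_GFF)
        return read_gff_genes(gff)

    def test_gff_parsed_into_intervals(self, genes):
        assert len(genes) == 4
        assert set(genes["name"]) == {"GENE1", "GENE2", "GENE3", "GENE4"}

    def test_snp_inside_gene_distance_zero(self, genes):
        snps = pd.DataFrame({"id": ["q1"], "chrom": ["1"], "pos": [1500]})
        ann = annotate_nearest_gene(snps, genes)
        assert ann["distance"].iloc[0] == 0 and ann["gene"].iloc[0] == "GENE1"

    def test_gene_at_higher_coordinate_positive_distance(self, genes):
        # gene [1000, 2000], SNP at 610 -> +390
        snps = pd.DataFrame({"id": ["q1"], "chrom": ["1"], "pos": [610]})
        ann = annotate_nearest_gene(snps, genes)
        assert ann["distance"].iloc[0] == 390

    def test_gene_at_lower_coordinate_negative_distance(self, genes):
        snps = pd.DataFrame({"id": ["q1"], "chrom": ["1"], "pos": [2500]})
        ann = annotate_nearest_gene(snps, genes)
        assert ann["distance"].iloc[0] == -500 and ann["gene"].iloc[0] == "GENE1"

    def test_equidistant_tie_goes_to_smaller_start(self, genes):
        snps = pd.DataFrame({"id": ["q1"], "chrom": ["2"], "pos": [500]})
        ann = annotate_nearest_gene(snps, genes)
        assert ann["gene"].iloc[0] == "GENE3"

    def test_chromosome_absent_from_annotation_warns(self, genes):
        snps = pd.DataFrame({"id": ["q1"], "chrom": ["9"], "pos": [100]})
        with pytest.warns(UserWarning, match="absent"):
            ann = annotate_nearest_gene(snps, genes)
        assert ann["gene"].iloc[0] is None


def test_plot_outputs_cover_all_snps(tmp_path):
    from heterogen.plots import manhattan_plot, qq_plot

    g, d = make_panel(80, 150, seed=99)
    Ga = additive_grm(d)
    y = np.random.default_rng(100).standard_normal(80)
    scan = scan_single_locus(y, None, d, Ga, "additive")
    th = bonferroni_thresholds(scan.n_tests)
    manhattan_plot(scan, th, tmp_path / "man.png")
    qq_plot(scan, tmp_path / "qq.png")
    assert (tmp_path / "man.png").stat().st_size > 0
    assert (tmp_path / "qq.png").stat().st_size > 0
    assert scan.n_tests == 150
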