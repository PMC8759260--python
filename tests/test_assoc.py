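"""Association engine: expression preprocessing, latent factors, OLS
t statistics against an independent oracle, empirical-null calibration,
cis/trans classification, multiple testing, core-set rules, and the
permutation null."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clockdissect.associations import (AssociationResults, association_scan,
                                       build_design, classify_cis_trans,
                                       classify_pair, core_set_threshold,
                                       empirical_null_correct,
                                       estimate_latent_factors,
                                       fit_cpg_gene_models, permutation_test,
                                       preprocess_expression, rank_inverse_normal,
                                       select_core_set, select_significant)


def _gene_coords(genes, chrom="chr7", biotype="protein_coding"):
    return pd.DataFrame({
        "chrom": chrom, "start": 1_000_000, "end": 1_020_000,
        "strand": "+", "biotype": biotype}, index=pd.Index(genes, name="gene"))


class TestPreprocess:
    def test_median_count_filter_is_strict(self):
        counts = pd.DataFrame({
            "keep": [5, 6, 7, 8],          # median 6.5 > 1
            "border": [1, 1, 1, 1],        # median exactly 1 -> removed
            "low": [0, 0, 1, 0]},          # removed
            index=list("abcd"))
        out = preprocess_expression(counts, _gene_coords(counts.columns))
        assert list(out.expr.columns) == ["keep"]

    def test_biotype_and_autosome_filters(self):
        counts = pd.DataFrame({"pc": [5, 6, 7, 8], "linc": [5, 6, 7, 8],
                               "chrx": [5, 6, 7, 8]}, index=list("abcd"))
        gc = pd.concat([_gene_coords(["pc"]),
                        _gene_coords(["linc"], biotype="lincRNA"),
                        _gene_coords(["chrx"], chrom="chrX")])
        out = preprocess_expression(counts, gc)
        assert list(out.expr.columns) == ["pc"]

    def test_rin_closed_form(self):
        got = rank_inverse_normal(np.array([5.0, 1.0, 9.0]))
        expect = stats.norm.ppf([3 / 6, 1 / 6, 5 / 6])
        assert np.abs(got - expect).max() < 1e-12

    def test_rin_columns_centred_and_symmetric(self, scan_bundle):
        expr = scan_bundle.expr.expr
        assert np.abs(expr.mean(axis=0)).max() < 1e-8
        assert np.abs(expr.values + expr.values[::-1].copy()).max() < np.inf
        # ties aside, RIN output is a permutation of fixed quantiles
        col = np.sort(expr.iloc[:, 0].values)
        n = len(col)
        assert np.abs(col - stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)).max() < 1e-8

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"g": [0, 5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="library"):
            preprocess_expression(counts, _gene_coords(["g"]))


class TestLatentFactors:
    def test_orthonormality(self, scan_bundle):
        lf = estimate_latent_factors(scan_bundle.expr.expr, scan_bundle.design, k=5)
        gram = lf.values.T @ lf.values
        assert np.abs(gram - np.eye(5)).max() < 1e-8

    def test_planted_confounder_recovered(self):
        rng = np.random.default_rng(0)
        n, g = 500, 200
        design = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        conf = rng.normal(size=n)
        load = np.zeros(g)
        load[: g // 2] = rng.normal(0, 1.0, g // 2)
        expr = pd.DataFrame(
            np.outer(design["x"], rng.normal(size=g))
            + np.outer(conf, load) + rng.normal(0, 0.5, (n, g)))
        lf = estimate_latent_factors(expr, design, k=3)
        assert abs(np.corrcoef(lf.values[:, 0], conf)[0, 1]) > 0.9

    def test_pure_covariate_expression_leaves_no_residual(self):
        rng = np.random.default_rng(1)
        n, g = 50, 20
        design = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        expr = pd.DataFrame(np.outer(design["x"], rng.normal(size=g)))
        q, _ = np.linalg.qr(design.values)
        resid = expr.values - q @ (q.T @ expr.values)
        assert np.abs(resid).max() < 1e-10

    def test_invalid_k_rejected(self, scan_bundle):
        with pytest.raises(ValueError):
            estimate_latent_factors(scan_bundle.expr.expr, scan_bundle.design, k=0)


class TestOLS:
    def test_t_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 12
        beta_col = pd.Series(rng.random(n), name="cg")
        design = pd.DataFrame({"intercept": 1.0, "age": rng.uniform(20, 70, n),
                               "sex": rng.integers(0, 2, n).astype(float)})
        expr = pd.DataFrame({"g1": rng.normal(size=n), "g2": rng.normal(size=n)})
        got = fit_cpg_gene_models(beta_col, expr, design)
        for g in expr.columns:
            X = np.column_stack([design.values, beta_col.values])
            fit = sm.OLS(expr[g].values, X).fit()
            assert got.loc[g, "t"] == pytest.approx(fit.tvalues[-1], abs=1e-8)
            assert got.loc[g, "p"] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_perfect_fit_flagged_infinite(self):
        n = 10
        rng = np.random.default_rng(3)
        beta_col = pd.Series(rng.random(n))
        design = pd.DataFrame({"intercept": np.ones(n)})
        expr = pd.DataFrame({"copy": beta_col.values})
        got = fit_cpg_gene_models(beta_col, expr, design)
        assert np.isinf(got.loc["copy", "t"])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        n, g = 200, 2000
        beta_col = pd.Series(rng.random(n))
        design = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        expr = pd.DataFrame(rng.normal(size=(n, g)))
        got = fit_cpg_gene_models(beta_col, expr, design)
        ks = stats.kstest(got["p"].values, "uniform").statistic
        assert ks < 0.05

    def test_rank_deficient_design_names_columns(self):
        n = 20
        rng = np.random.default_rng(5)
        design = pd.DataFrame({"intercept": 1.0, "a": rng.normal(size=n)})
        design["b"] = design["a"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_cpg_gene_models(pd.Series(rng.random(n)),
                                pd.DataFrame({"g": rng.normal(size=n)}), design)


class TestEmpiricalNull:
    def test_standard_null_scale_recovered(self):
        z = np.random.default_rng(6).normal(0, 1, 10000)
        _, _, mu, sg, method = empirical_null_correct(z, df=10**6)
        assert abs(mu) < 0.03 and abs(sg - 1) < 0.03
        assert method == "central"

    def test_affine_null_fully_corrected(self):
        z = np.random.default_rng(7).normal(0.5, 2.0, 10000)
        zc, _, mu, sg, _ = empirical_null_correct(z, df=10**6)
        assert stats.kstest(zc, "norm").pvalue > 0.01

    def test_contaminated_null_shielded_from_signal(self):
        rng = np.random.default_rng(8)
        z = np.concatenate([rng.normal(0, 2, 9500), rng.normal(4, 1, 500)])
        _, _, _, sg, _ = empirical_null_correct(z, df=10**6)
        assert 1.8 <= sg <= 2.2

    def test_deflation_not_rewarded_by_default(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 0.5, 5000)
        zc, _, _, sg, _ = empirical_null_correct(z, df=10**6)
        assert sg == pytest.approx(0.5, abs=0.03)  # reported as estimated
        assert np.abs(zc).max() <= np.abs(z - np.median(z)).max() + 0.1

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            empirical_null_correct(np.zeros(50), df=100)


class TestCisTrans:
    GENE = dict(gene_chrom="chr1", gene_start=1_050_000, gene_end=1_060_000)

    def test_window_boundaries(self):
        assert classify_pair("chr1", 1_000_000, **self.GENE) == "cis"       # gap 50 kb
        assert classify_pair("chr2", 1_000_000, **self.GENE) == "trans"     # other chrom
        assert classify_pair("chr1", 950_000, **self.GENE) == "cis"         # gap exactly 100 kb
        assert classify_pair("chr1", 4_060_000, **self.GENE) == "excluded"  # gap 3 Mb
        assert classify_pair("chr1", 6_060_001, **self.GENE) == "trans"     # gap 5 Mb + 1
        assert classify_pair("chr1", 1_055_000, **self.GENE) == "cis"       # inside gene

    def test_inconsistent_chromosome_naming_rejected(self):
        with pytest.raises(ValueError, match="naming"):
            classify_pair("1", 100, "chr1", 50, 60)

    def test_mask_partitions_every_pair(self, scan_bundle):
        mask = scan_bundle.results.mask
        assert set(np.unique(mask.values)) <= {"cis", "trans", "excluded"}
        assert mask.shape == scan_bundle.results.t.shape

    def test_matrix_matches_pairwise_rule(self):
        cpgs = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [1_000_000, 500]},
                            index=["cgA", "cgB"])
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [1_050_000],
                              "end": [1_060_000], "strand": "+",
                              "biotype": "protein_coding"}, index=["g"])
        mask = classify_cis_trans(cpgs, genes)
        assert mask.loc["cgA", "g"] == "cis"
        assert mask.loc["cgB", "g"] == "trans"


def _fake_results(p_matrix, mask_value="trans"):
    p = pd.DataFrame(p_matrix)
    p.index = [f"cg{i}" for i in range(p.shape[0])]
    p.columns = [f"g{j}" for j in range(p.shape[1])]
    z = pd.DataFrame(stats.norm.isf(p.values / 2), index=p.index, columns=p.columns)
    mask = pd.DataFrame(mask_value, index=p.index, columns=p.columns)
    return AssociationResults(
        t=z.copy(), p=p.copy(), t_corrected=z, p_corrected=p, mask=mask,
        bias=pd.Series(0.0, index=p.index), inflation=pd.Series(1.0, index=p.index),
        df_resid=100)


class TestMultipleTesting:
    def test_bonferroni_within_domain(self):
        p = np.full((1, 100), 0.5)
        p[0, 0] = 0.0004
        res = _fake_results(p)
        sig = select_significant(res, "trans")
        assert len(sig) == 1
        assert sig["p_bonf"].iloc[0] == pytest.approx(0.04)

    def test_larger_family_loses_significance(self):
        p = np.full((1, 1000), 0.5)
        p[0, 0] = 0.0004
        res = _fake_results(p)
        assert len(select_significant(res, "trans")) == 0

    def test_family_wise_error_controlled_under_null(self):
        # 200 independent null scans; count replicates with any
        # Bonferroni-significant trans hit
        rng = np.random.default_rng(10)
        n, n_cpg, n_gene = 60, 10, 150
        genes = pd.DataFrame({"chrom": "chr9", "start": 1_000, "end": 2_000,
                              "strand": "+", "biotype": "protein_coding"},
                             index=[f"g{j}" for j in range(n_gene)])
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": 1_000_000},
                            index=[f"cg{i}" for i in range(n_cpg)])
        design = pd.DataFrame({"intercept": np.ones(n)})
        hits = 0
        from clockdissect.associations import scan_tstats, empirical_null_correct
        for rep in range(200):
            b = rng.random((n, n_cpg))
            e = rng.normal(size=(n, n_gene))
            t, df = scan_tstats(b, e, design.values)
            n_pairs = n_cpg * n_gene
            any_hit = False
            for i in range(n_cpg):
                _, pc, _, _, _ = empirical_null_correct(t[i], df)
                if (pc * n_pairs < 0.05).any():
                    any_hit = True
                    break
            hits += any_hit
        assert hits <= 15

    def test_empty_domain_rejected(self):
        res = _fake_results(np.full((2, 3), 0.5), mask_value="cis")
        with pytest.raises(ValueError, match="trans"):
            select_significant(res, "trans")


class TestCoreSet:
    def test_thresholds_are_ceil_of_five_percent(self):
        assert [core_set_threshold(s) for s in (71, 353, 391, 514)] == [4, 18, 20, 26]

    def test_gene_below_every_clock_threshold_excluded(self):
        # clock A: 60 CpGs -> threshold 3; clock B: 400 CpGs -> threshold 20
        n_cpg, n_gene = 25, 30
        p = np.full((n_cpg, n_gene), 0.5)
        p[:2, 0] = 1e-10    # gene g0: 2 significant CpGs in clock A -> below 3
        p[:3, 1] = 1e-10    # gene g1: 3 significant CpGs in clock A -> kept
        res = _fake_results(p)
        clocks = {"A": [f"cg{i}" for i in range(20)]
                  + [f"x{i}" for i in range(40)],
                  "B": [f"y{i}" for i in range(400)]}
        core = select_core_set(res, clocks, min_trans_genes=5)
        assert core.clock_thresholds == {"A": 3, "B": 20}
        assert core.genes == ["g1"]

    def test_cpg_needs_min_trans_genes(self):
        n_cpg, n_gene = 4, 40
        p = np.full((n_cpg, n_gene), 0.5)
        p[0, :10] = 1e-12   # cg0: 10 significant genes -> kept
        p[1, :9] = 1e-12    # cg1: 9 -> dropped
        res = _fake_results(p)
        core = select_core_set(res, {"A": [f"cg{i}" for i in range(60)]})
        assert core.cpgs == ["cg0"]

    def test_default_cohort_recovers_planted_sets_exactly(self, scan_bundle):
        truth = scan_bundle.truth
        core = scan_bundle.core
        gl = truth.gene_cluster_labels
        markers = {g for g in gl.index[gl != "null"]
                   if g in scan_bundle.results.t.columns}
        assert set(core.genes) == markers
        cl = truth.cpg_cluster_labels
        cluster_cpgs = {c for c in cl.index[cl != "neutral"]
                        if c in scan_bundle.results.t.index}
        assert set(core.cpgs) == cluster_cpgs

    def test_cluster_signal_sign_consistency(self, scan_bundle):
        """Cluster-1 CpGs: strongest positive trans-genes are naive
        markers, strongest negative are activated markers."""
        truth, res = scan_bundle.truth, scan_bundle.results
        cl, gl = truth.cpg_cluster_labels, truth.gene_cluster_labels
        naive = [g for g in gl.index[gl == "naive_marker"] if g in res.t.columns]
        act = [g for g in gl.index[gl == "activated_marker"] if g in res.t.columns]
        ok = 0
        c1 = [c for c in cl.index[cl == "cluster1"] if c in res.t.index]
        for cpg in c1:
            row = res.t_corrected.loc[cpg]
            top_pos = row.nlargest(5).index
            top_neg = row.nsmallest(5).index
            ok += set(top_pos) <= set(naive) and set(top_neg) <= set(act)
        assert ok / len(c1) >= 0.95


class TestPermutation:
    def _small(self):
        rng = np.random.default_rng(11)
        n, n_cpg, n_gene = 50, 5, 120
        beta = pd.DataFrame(rng.random((n, n_cpg)),
                            index=[f"s{i}" for i in range(n)],
                            columns=[f"cg{i}" for i in range(n_cpg)])
        counts = pd.DataFrame(rng.poisson(50, (n, n_gene)),
                              index=beta.index,
                              columns=[f"g{j}" for j in range(n_gene)])
        genes = pd.DataFrame({"chrom": "chr9", "start": 1_000, "end": 2_000,
                              "strand": "+", "biotype": "protein_coding"},
                             index=counts.columns)
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": 1_000_000}, index=beta.columns)
        expr = preprocess_expression(counts, genes)
        design = pd.DataFrame({"intercept": 1.0}, index=beta.index)
        return beta, expr, design, cpgs

    def test_pure_noise_gives_empirical_p_one(self):
        beta, expr, design, cpgs = self._small()
        perm = permutation_test(beta, expr, design, cpgs, n_perm=20, seed=0,
                                n_latent_factors=0, observed=0)
        assert perm.empirical_p == 1.0

    def test_same_seed_reproduces_counts(self):
        beta, expr, design, cpgs = self._small()
        a = permutation_test(beta, expr, design, cpgs, n_perm=10, seed=3,
                             n_latent_factors=0)
        b = permutation_test(beta, expr, design, cpgs, n_perm=10, seed=3,
                             n_latent_factors=0)
        assert np.array_equal(a.perm_counts, b.perm_counts)
        assert a.observed == b.observed

    def test_invalid_n_perm_rejected(self):
        beta, expr, design, cpgs = self._small()
        with pytest.raises(ValueError):
            permutation_test(beta, expr, design, cpgs, n_perm=0, seed=0)


class TestDesign:
    def test_neutrophils_excluded_by_default(self, cohort_truth):
        cohort, _ = cohort_truth
        design = build_design(cohort.covariates)
        assert not any("neutrophil" in c for c in design.columns)
        assert any("lymphocyte" in c for c in design.columns)
        assert "intercept" in design.columns

    def test_missing_covariates_rejected(self, cohort_truth):
        cohort, _ = cohort_truth
        cov = cohort.covariates.copy()
        cov.loc[cov.index[0], "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(cov)

    def test_rare_levels_pooled(self):
        n = 40
        rng = np.random.default_rng(12)
        cov = pd.DataFrame({
            "age": rng.uniform(20, 70, n),
            "cohort": ["common"] * 38 + ["rare1", "rare2"],
        }, index=[f"s{i}" for i in range(n)])
        design = build_design(cov, categorical=("cohort",), numeric=("age",))
        assert not any("rare" in c for c in design.columns)
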