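import numpy as np
import pandas as pd
import pytest

from rnapopstruct import popstruct, strat_dge, synthsim
from rnapopstruct.popstruct import GRM
from rnapopstruct.strat_dge import (
    ExpressionMatrix,
    cpm_filter,
    dge_lm,
    inflation_m,
    lmm_scan,
    reml_lmm,
)


def _expr(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))


class TestCpmFilter:
    def test_all_zero_gene_removed(self):
        expr = _expr([[0] * 10, [100] * 10])
        out = cpm_filter(expr)
        assert out.gene_ids == ["g1"]

    def test_boundary_count_is_kept(self):
        # 10 samples, threshold fraction 0.2 -> need ceil(2) = 2 samples
        counts = np.ones((2, 10), dtype=int) * 1000
        counts[0] = 0
        counts[0, :2] = 1000  # exceeds CPM threshold in exactly 2 samples
        out = cpm_filter(_expr(counts), cpm_min=0.05, sample_frac=0.2)
        assert "g0" in out.gene_ids

    def test_autosomal_filter(self):
        expr = _expr([[100] * 4, [100] * 4])
        chrom = pd.Series({"g0": "1", "g1": "X"})
        out = cpm_filter(expr, gene_chrom=chrom, autosomal_only=True)
        assert out.gene_ids == ["g0"]

    def test_zero_library_size_names_sample(self):
        expr = _expr([[0, 100], [0, 100]], samples=["bad", "good"])
        with pytest.raises(ValueError, match="bad"):
            cpm_filter(expr)


class TestDgeLm:
    def _null_study(self, n=100, genes=500, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.negative_binomial(10, 0.1, size=(genes, n))
        trait = rng.integers(0, 2, n).astype(float)
        return _expr(counts), trait

    def test_collinear_design_rejected(self):
        expr, trait = self._null_study()
        cov = pd.DataFrame({"dup": trait})
        with pytest.raises(ValueError, match="collinear"):
            dge_lm(expr, trait, cov)

    def test_degenerate_gene_flagged(self):
        rng = np.random.default_rng(1)
        n = 40
        trait = rng.integers(0, 2, n).astype(float)
        lib = np.full(n, 1_000_000)
        # gene counts exactly determined by trait
        counts = np.vstack([np.where(trait > 0, 4000, 1000), lib - 4000])
        expr = _expr(counts.astype(int))
        res = dge_lm(expr, trait)
        assert res.table["flagged"].iloc[0]
        assert np.isfinite(res.table["chisq"].iloc[0])

    def test_zero_pcs_equals_absent_pcs(self):
        expr, trait = self._null_study(seed=2)
        r1 = dge_lm(expr, trait, None, None)
        r2 = dge_lm(expr, trait, None, np.zeros((len(trait), 0)))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_type_i_error_near_nominal(self):
        """Null genes, no confounding: fraction of p < 0.05 within binomial
        tolerance of 0.05."""
        rng = np.random.default_rng(3)
        n, genes = 100, 2000
        labels = np.zeros(n, dtype=int)
        sex = rng.integers(0, 2, n)
        counts, _ = synthsim.simulate_counts(
            labels,
            sex * 0,  # no sex effect used below; trait drawn independently
            synthsim.ExpressionModel(
                n_genes=genes, frac_confounded=0.0, frac_sex_de=0.0, seed=4
            ),
        )
        trait = rng.integers(0, 2, n).astype(float)
        res = dge_lm(ExpressionMatrix(counts), trait)
        frac = (res.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / genes) + 0.01

    def test_bh_counts_reproducible_from_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        expr, trait = self._null_study(seed=5)
        res = dge_lm(expr, trait)
        q = multipletests(res.table["p"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(res.table["q"].to_numpy(), q)
        assert res.n_significant(0.05, use_fdr=True) == int((q < 0.05).sum())

    def test_constant_extra_gene_leaves_others_unchanged(self):
        expr, trait = self._null_study(n=50, genes=20, seed=6)
        lib = expr.library_sizes
        expr = ExpressionMatrix(expr.counts, lib)
        res1 = dge_lm(expr, trait)
        counts2 = pd.concat(
            [expr.counts, pd.DataFrame([[50] * 50], index=["flat"], columns=expr.counts.columns)]
        )
        res2 = dge_lm(ExpressionMatrix(counts2, lib), trait)
        # p-values of original genes unchanged (q-values change with the set)
        np.testing.assert_allclose(
            res1.table["p"].to_numpy(), res2.table["p"].to_numpy()[:-1], rtol=1e-10
        )


class TestInflationM:
    def _res(self, chisq):
        p = 1 - 0.5 * np.ones(len(chisq))  # placeholder p; only chisq is used
        t = pd.DataFrame(
            {"logFC": 0.0, "se": 1.0, "t": 0.0, "p": p, "chisq": chisq, "q": p, "flagged": False},
            index=pd.Index([f"g{i}" for i in range(len(chisq))], name="gene"),
        )
        return strat_dge.DGEResult(t)

    def test_identical_inputs_give_one(self):
        r = self._res(np.random.default_rng(0).chisquare(1, 100))
        assert inflation_m(r, r).m == 1.0

    def test_scaled_statistics_give_the_scale(self):
        chisq = np.random.default_rng(1).chisquare(1, 501)
        r_without = self._res(chisq)
        r_with = self._res(0.935 * chisq)
        assert inflation_m(r_with, r_without).m == pytest.approx(0.935, abs=1e-12)

    def test_gene_set_mismatch_rejected(self):
        a = self._res(np.ones(3))
        b = strat_dge.DGEResult(a.table.iloc[:2])
        with pytest.raises(ValueError):
            inflation_m(a, b)

    def test_confounded_scenario_reduces_m(self):
        """Sex imbalanced across populations with confounded genes: adjusting
        for genotype PCs deflates the sex-association statistics (m < 1)."""
        full, labels = synthsim.simulate_genotypes(
            synthsim.PopulationModel(k=2, fst=0.1, n_per_pop=60, n_variants=1000, seed=7)
        )
        sex = synthsim.simulate_sex(labels, imbalance=0.3, seed=8)
        counts, _ = synthsim.simulate_counts(
            labels, sex, synthsim.ExpressionModel(n_genes=800, frac_confounded=0.15, seed=9)
        )
        maf = __import__("rnapopstruct").variant_qc.compute_variant_stats(
            full, with_hwe=False
        ).maf
        pcs = popstruct.pca(full.take_variants(np.nonzero(maf > 0.01)[0]), 2).scores
        expr = ExpressionMatrix(counts)
        with_pcs = dge_lm(expr, sex.astype(float), None, pcs)
        without = dge_lm(expr, sex.astype(float), None, None)
        assert inflation_m(with_pcs, without).m < 1


class TestRemlLmm:
    def test_grm_identity_limit_matches_ols(self):
        rng = np.random.default_rng(10)
        n = 80
        x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = x @ np.array([1.0, 0.4, -0.3]) + rng.normal(size=n)
        grm = GRM(np.eye(n), 1, [f"s{i}" for i in range(n)])
        fit = reml_lmm(y, x, grm)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        resid = y - x @ beta
        s2 = (resid**2).sum() / (n - 3)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(s2, abs=1e-6)
        cov = np.linalg.inv(x.T @ x) * s2
        wald = (beta / np.sqrt(np.diag(cov))) ** 2
        np.testing.assert_allclose(fit.wald_chisq, wald, atol=1e-6)

    def test_zero_heritability_truth_recovers_boundary(self):
        full, _ = synthsim.simulate_genotypes(
            synthsim.PopulationModel(k=2, fst=0.1, n_per_pop=60, n_variants=1000, seed=11)
        )
        maf = __import__("rnapopstruct").variant_qc.compute_variant_stats(
            full, with_hwe=False
        ).maf
        grm = popstruct.compute_grm(
            popstruct.standardize(full.take_variants(np.nonzero(maf > 0)[0]))
        )
        rng = np.random.default_rng(12)
        n = full.n_samples
        ratios = [
            reml_lmm(rng.normal(size=n), np.ones((n, 1)), grm).ratio
            for _ in range(10)
        ]
        assert np.median(ratios) < 0.1

    def test_non_psd_grm_rejected(self):
        m = np.eye(4)
        m[0, 0] = -1.0
        grm = GRM(m, 1, list("abcd"))
        with pytest.raises(ValueError, match="positive semidefinite"):
            reml_lmm(np.zeros(4), np.ones((4, 1)), grm)


class TestLmmScan:
    def _structured(self, seed=13):
        full, labels = synthsim.simulate_genotypes(
            synthsim.PopulationModel(k=2, fst=0.1, n_per_pop=75, n_variants=1200, seed=seed)
        )
        from rnapopstruct.variant_qc import compute_variant_stats

        maf = compute_variant_stats(full, with_hwe=False).maf
        full = full.take_variants(np.nonzero(maf > 0.01)[0])
        return full, labels

    def test_identity_grm_scan_equals_ols_scan(self):
        full, _ = self._structured()
        n = full.n_samples
        rng = np.random.default_rng(14)
        y = rng.normal(size=n)
        grm = GRM(np.eye(n), 1, list(full.samples))
        scan = lmm_scan(y, full, grm)
        # OLS per-variant chi-square with sigma^2 from the intercept-only null
        yc = y - y.mean()
        s2 = yc @ yc / (n - 1)
        g = np.where(full.dosage == -1, 0, full.dosage).astype(float)
        gc = g - g.mean(axis=0)
        gg = (gc**2).sum(axis=0)
        beta = gc.T @ yc / gg
        chi2 = beta**2 * gg / s2
        np.testing.assert_allclose(scan["chisq"], chi2, atol=1e-6)

    def test_null_phenotype_median_near_expected(self):
        full, _ = self._structured(seed=15)
        y = np.random.default_rng(16).normal(size=full.n_samples)
        grm = popstruct.compute_grm(popstruct.standardize(full))
        scan = lmm_scan(y, full, grm)
        med = np.median(scan["chisq"])
        assert 0.30 < med < 0.62  # 1-df chi-square median is 0.4549

    def test_confounded_phenotype_inflates_then_pcs_deflate(self):
        full, labels = self._structured(seed=17)
        n = full.n_samples
        rng = np.random.default_rng(18)
        y = labels.astype(float) + 0.8 * rng.normal(size=n)
        identity = GRM(np.eye(n), 1, list(full.samples))
        naive = lmm_scan(y, full, identity)
        assert np.median(naive["chisq"]) > 0.6  # stratification inflates
        pcs = popstruct.pca(full, 1).scores
        adj = lmm_scan(y, full, identity, pcs=pcs)
        m = np.median(adj["chisq"]) / np.median(naive["chisq"])
        assert m < 1
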