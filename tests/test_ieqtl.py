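import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellregvar import simulate as sim
from cellregvar.ieqtl import (GenotypeMatrix, adjust_pvalues,
                              classify_negative_ieqtl, compute_maf,
                              effective_tests, filter_fractions,
                              filter_genes, fit_interaction_model,
                              inverse_normal_transform, map_cis_ieqtls,
                              tmm_normalize)


class TestGeneFilter:
    def test_all_zero_gene_dropped(self):
        tpm = pd.DataFrame({"s1": [0.0, 1.0], "s2": [0.0, 1.0]},
                           index=["g1", "g2"])
        counts = pd.DataFrame({"s1": [0, 50], "s2": [0, 50]},
                              index=["g1", "g2"])
        assert filter_genes(tpm, counts) == ["g2"]

    def test_thresholds_are_inclusive(self):
        # 10 samples; TPM >= 0.1 in exactly 2 (=20%) and counts >= 6 in 2
        tpm = pd.DataFrame([np.r_[[0.1, 0.1], np.zeros(8)]], index=["g"])
        counts = pd.DataFrame([np.r_[[6, 6], np.zeros(8)]], index=["g"])
        tpm.columns = counts.columns = [f"s{i}" for i in range(10)]
        assert filter_genes(tpm, counts) == ["g"]

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        tpm = pd.DataFrame(rng.exponential(0.2, size=(50, 10)),
                           index=[f"g{i}" for i in range(50)])
        counts = pd.DataFrame(rng.poisson(5, size=(50, 10)),
                              index=tpm.index)
        kept = filter_genes(tpm, counts)
        expected = [g for g in tpm.index
                    if (tpm.loc[g] >= 0.1).sum() >= 2
                    and (counts.loc[g] >= 6).sum() >= 2]
        assert kept == expected

    def test_gene_mismatch_rejected(self):
        tpm = pd.DataFrame({"s": [1.0]}, index=["g1"])
        counts = pd.DataFrame({"s": [1]}, index=["g2"])
        with pytest.raises(ValueError):
            filter_genes(tpm, counts)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([10, 20, 30, 5, 0, 100])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        factors, _ = tmm_normalize(counts)
        np.testing.assert_allclose(factors, 1.0, atol=1e-12)

    def test_pure_depth_difference_has_unit_factor_ratio(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(20, size=300)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        factors, _ = tmm_normalize(counts)
        # M-values are constant, so the trimmed mean is the same log ratio
        # for both; after geometric rescaling the ratio is 1
        assert factors["a"] / factors["b"] == pytest.approx(1.0, abs=1e-9)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(10, size=(200, 4)),
                              columns=list("abcd"))
        f1, _ = tmm_normalize(counts)
        f2, _ = tmm_normalize(counts[["d", "b", "a", "c"]])
        for s in "abcd":
            assert f1[s] == pytest.approx(f2[s], abs=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_normalize(counts)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_edger_reference_implementation(self):
        """Independent oracle: edgeR's TMM factors on a random fixture."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.3, size=(200, 5)),
                              columns=list("ABCDE"))
        counts.iloc[:20, 0] *= 5  # composition shift
        factors, _ = tmm_normalize(counts)
        with tempfile.TemporaryDirectory() as td:
            counts.to_csv(f"{td}/c.tsv", sep="\t", index=False)
            res = subprocess.run(
                ["Rscript", "-e",
                 'suppressMessages(library(edgeR)); '
                 f'x<-as.matrix(read.delim("{td}/c.tsv")); '
                 'cat(calcNormFactors(x,method="TMM"),sep="\\n")'],
                capture_output=True, text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(factors.to_numpy(), edger, atol=1e-5)


class TestInverseNormalTransform:
    def test_three_point_quantile_oracle(self):
        out = inverse_normal_transform([5.0, 1.0, 3.0])
        expected = stats.norm.ppf([(r - 0.5) / 3 for r in (3, 1, 2)])
        np.testing.assert_allclose(out, expected, atol=1e-10)
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(0.96742, abs=1e-4)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=100)
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.log(x)),
                                   atol=1e-12)

    def test_large_sample_moments(self):
        rng = np.random.default_rng(5)
        out = inverse_normal_transform(rng.normal(size=5000))
        assert abs(out.mean()) < 1e-8
        assert out.std() == pytest.approx(1.0, abs=0.02)

    def test_all_tied_maps_to_zero(self):
        np.testing.assert_array_equal(
            inverse_normal_transform([2.0, 2.0, 2.0, 2.0]), 0.0)

    def test_ties_share_average_rank(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == out[2]


class TestFractionFilter:
    def test_low_scores_dropped(self):
        scores = pd.DataFrame({"c1": [0.5] * 10})
        assert filter_fractions(scores) == []

    def test_exactly_one_fifth_is_not_enough(self):
        col = np.r_[[1.5, 1.5], np.zeros(8)]
        assert filter_fractions(pd.DataFrame({"c1": col})) == []

    def test_more_than_one_fifth_kept(self):
        col = np.r_[[1.5, 1.5, 1.5], np.zeros(7)]
        assert filter_fractions(pd.DataFrame({"c1": col})) == ["c1"]


class TestInteractionModel:
    def test_noiseless_interaction_recovered_exactly(self):
        rng = np.random.default_rng(6)
        n = 60
        g = rng.binomial(2, 0.4, n).astype(float)
        f = rng.normal(size=n)
        y = 2.0 * g * f
        fit = fit_interaction_model(y, g, f)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-10)
        assert fit.p_interaction < 1e-30

    def test_matches_normal_equation_solution(self):
        # small worked dataset, solved directly via the normal equations
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        f = np.array([-1.2, 0.3, 0.8, 1.5, -0.7, 0.1, 0.9, -0.4])
        y = np.array([0.2, 1.1, 2.3, -0.5, 0.7, 1.9, 1.4, 0.1])
        fit = fit_interaction_model(y, g, f)
        X = np.column_stack([np.ones(8), g, f, g * f])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.beta2 == pytest.approx(beta[1], abs=1e-10)
        assert fit.beta3 == pytest.approx(beta[2], abs=1e-10)
        assert fit.beta1 == pytest.approx(beta[3], abs=1e-10)
        # and the t/p from the standard OLS covariance
        resid = y - X @ beta
        sigma2 = resid @ resid / (8 - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        t = beta[3] / se[3]
        assert fit.t1 == pytest.approx(t, abs=1e-10)
        assert fit.p_interaction == pytest.approx(
            2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 80
        g = rng.binomial(2, 0.3, n).astype(float)
        f = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        y = 0.5 * g * f + 0.2 * g + C @ [0.3, -0.1] + rng.normal(size=n)
        fit = fit_interaction_model(y, g, f, C)
        X = sm.add_constant(np.column_stack([g, f, g * f, C]))
        res = sm.OLS(y, X).fit()
        assert fit.beta1 == pytest.approx(res.params[3], abs=1e-10)
        assert fit.p_interaction == pytest.approx(res.pvalues[3], abs=1e-10)

    def test_collinear_design_rejected(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_interaction_model(np.arange(6.0), g, g)  # f == g


class TestCisMapping:
    def test_single_cis_variant_is_top(self, genotypes_200):
        gm = genotypes_200
        vid = gm.dosages.columns[0]
        pos = int(gm.variants.loc[vid, "pos"])
        rng = np.random.default_rng(8)
        y = rng.normal(size=200)
        f = rng.normal(size=200)
        # window covering only the first variant
        _, rec = map_cis_ieqtls("g", "chr1", pos, y, gm, f, window_bp=100)
        assert rec.variant_id == vid
        assert rec.n_cis_variants == 1

    def test_window_boundary_is_closed(self, genotypes_200):
        gm = genotypes_200
        pos = gm.variants["pos"].to_numpy()
        tss = int(pos[0])
        window = int(pos[3] - pos[0])  # boundary falls exactly on variant 3
        from cellregvar.ieqtl import cis_window_variants

        ids = cis_window_variants(gm, "chr1", tss, window, maf_floor=0.0)
        assert gm.dosages.columns[3] in ids

    def test_planted_variant_recovered(self):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            gm = sim.gen_genotypes(300, 12, ld_block=1, maf_low=0.2,
                                   maf_high=0.4, seed=100 + rep)
            causal = gm.dosages.columns[4]
            y, fr, C, _ = sim.gen_ieqtl_cohort(gm, beta1=0.8, beta2=0.2,
                                               beta3=0.1, causal_variant=causal,
                                               noise_sd=1.0, seed=rep)
            f = inverse_normal_transform(fr)
            _, rec = map_cis_ieqtls("g", "chr1", 15_000, y.to_numpy(), gm, f,
                                    C.to_numpy())
            hits += rec.variant_id == causal
        assert hits / n_rep >= 0.9

    def test_empty_window_returns_none(self, genotypes_200):
        rng = np.random.default_rng(9)
        table, rec = map_cis_ieqtls("g", "chr2", 1, rng.normal(size=200),
                                    genotypes_200, rng.normal(size=200))
        assert rec is None and table.empty


class TestEffectiveTests:
    def test_independent_variants_keep_full_count(self):
        rng = np.random.default_rng(10)
        dos = pd.DataFrame(rng.binomial(2, 0.5, size=(5000, 8)).astype(float))
        m = effective_tests(dos)
        assert m >= 7  # essentially no correlation to absorb

    def test_duplicated_variants_collapse_to_one(self):
        rng = np.random.default_rng(11)
        col = rng.binomial(2, 0.4, 200).astype(float)
        dos = pd.DataFrame({f"v{i}": col for i in range(6)})
        assert effective_tests(dos) == 1

    def test_three_variant_eigen_oracle(self):
        # construct dosages with known correlation ~0.8 between pairs
        rng = np.random.default_rng(12)
        n = 20_000
        base = rng.normal(size=n)
        cols = {}
        for i in range(3):
            cols[f"v{i}"] = 0.8 * base + 0.6 * rng.normal(size=n)
        dos = pd.DataFrame(cols)
        corr = np.corrcoef(dos.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        cum = np.cumsum(evals)
        expected = int(np.searchsorted(cum, 0.99 * evals.sum()) + 1)
        assert effective_tests(dos) == expected

    def test_invariant_under_reordering_within_window(self):
        rng = np.random.default_rng(13)
        dos = pd.DataFrame(rng.binomial(2, 0.3, size=(300, 10)).astype(float),
                           columns=[f"v{i}" for i in range(10)])
        m1 = effective_tests(dos)
        perm = rng.permutation(dos.columns)
        m2 = effective_tests(dos[perm])
        assert m1 == m2

    def test_bounded_by_variant_count(self, genotypes_200):
        m = effective_tests(genotypes_200.dosages)
        assert 1 <= m <= genotypes_200.dosages.shape[1]


class TestPvalueAdjustment:
    def test_bh_step_up_oracle(self):
        p = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03})
        m = pd.Series({"a": 1, "b": 1, "c": 1})
        out = adjust_pvalues(p, m)
        np.testing.assert_allclose(out["pval_adj_bh"], [0.03, 0.03, 0.03])

    def test_single_gene_bh_equals_emt(self):
        out = adjust_pvalues(pd.Series({"a": 0.004}), pd.Series({"a": 7}))
        assert out.loc["a", "pval_emt"] == pytest.approx(0.028)
        assert out.loc["a", "pval_adj_bh"] == pytest.approx(0.028)

    def test_bonferroni_capped_at_one(self):
        out = adjust_pvalues(pd.Series({"a": 0.3}), pd.Series({"a": 10}))
        assert out.loc["a", "pval_emt"] == 1.0

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(14)
        p = pd.Series(rng.uniform(size=20), index=[f"g{i}" for i in range(20)])
        m = pd.Series(rng.integers(1, 50, size=20), index=p.index)
        base = adjust_pvalues(p, m)["pval_adj_bh"]
        p2 = p.copy()
        p2.iloc[5] = min(1.0, p2.iloc[5] * 2)
        bumped = adjust_pvalues(p2, m)["pval_adj_bh"]
        assert (bumped >= base - 1e-12).all()


class TestNegativeIeqtl:
    def _cohort(self, slope, n=400, seed=15, flip=False):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.4, n).astype(float)
        f = rng.uniform(size=n)
        eff = 1.0 + slope * f  # genotype effect varies with fraction
        if flip:
            eff = np.where(f > 0.5, -1.0, 1.0)
        y = eff * g + 0.05 * rng.normal(size=n)
        return y, g, f

    def test_shrinking_effect_is_flagged(self):
        y, g, f = self._cohort(slope=-0.8)
        assert classify_negative_ieqtl(y, g, f) is True

    def test_growing_effect_not_flagged(self):
        y, g, f = self._cohort(slope=+0.8)
        assert classify_negative_ieqtl(y, g, f) is False

    def test_sign_flip_not_flagged(self):
        y, g, f = self._cohort(slope=0.0, flip=True)
        assert classify_negative_ieqtl(y, g, f) is False

    def test_small_bins_undetermined(self):
        y, g, f = self._cohort(slope=-0.8, n=20)
        assert classify_negative_ieqtl(y, g, f, min_per_bin=10) is None


class TestMaf:
    def test_maf_definition(self):
        dos = pd.DataFrame({"v1": [2, 2, 2, 1], "v2": [0, 0, 0, 1]})
        maf = compute_maf(dos)
        assert maf["v1"] == pytest.approx(1 - 7 / 8)
        assert maf["v2"] == pytest.approx(1 / 8)
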