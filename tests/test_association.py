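import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from protomix.association import (
    cis_assoc,
    clinical_multivariate,
    pathway_score,
    r2_decomposition,
    trans_assoc,
)


def null_trans_cohort(rng, n=60, n_genes=150):
    samples = [f"S{i}" for i in range(n)]
    genes = [f"G{i}" for i in range(n_genes)]
    feature = pd.Series(rng.integers(0, 2, n).astype(float), index=samples)
    traits = pd.DataFrame(rng.normal(0, 1, (n_genes, n)), index=genes,
                          columns=samples)
    cov = pd.DataFrame({"age": rng.normal(0, 1, n),
                        "purity": rng.uniform(0.3, 0.9, n)}, index=samples)
    return feature, traits, cov


class TestTransAssoc:
    def test_t_matches_least_squares_oracle(self, rng):
        feature, traits, cov = null_trans_cohort(rng, n=40, n_genes=10)
        res = trans_assoc(feature, traits, cov, n_perm=10, seed=0, normalize=False)
        for g in traits.index:
            y = traits.loc[g].to_numpy(dtype=float)
            X = np.column_stack([np.ones(40), feature.to_numpy(),
                                 cov["age"], cov["purity"]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = resid @ resid / (40 - 4)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res.loc[g, "t"] == pytest.approx(beta[1] / se, rel=1e-9)

    def test_planted_negative_effect_power(self):
        rng = np.random.default_rng(31)
        n, n_genes = 100, 400
        samples = [f"S{i}" for i in range(n)]
        genes = [f"G{i}" for i in range(n_genes)]
        feature = pd.Series((rng.random(n) < 0.5).astype(float), index=samples)
        Y = rng.normal(0, 1, (n_genes, n))
        Y[:100] += -0.8 * feature.to_numpy()
        traits = pd.DataFrame(Y, index=genes, columns=samples)
        res = trans_assoc(feature, traits, None, n_perm=50, seed=1)
        planted = set(genes[:100])
        hits = planted & set(res.index[res["significant"]])
        assert len(hits) >= 80
        assert (res.loc[sorted(hits), "direction"] == "negative").all()

    def test_constant_feature_errors(self, rng):
        _, traits, cov = null_trans_cohort(rng, n=20, n_genes=10)
        feature = pd.Series(1.0, index=traits.columns)
        with pytest.raises(ValueError):
            trans_assoc(feature, traits, cov)

    def test_permutation_invariance_of_t_under_joint_shuffle(self, rng):
        feature, traits, cov = null_trans_cohort(rng, n=30, n_genes=5)
        res1 = trans_assoc(feature, traits, cov, n_perm=10, seed=0)
        order = rng.permutation(len(feature))
        cols = traits.columns.to_numpy()[order]
        res2 = trans_assoc(feature.loc[cols], traits[cols], cov.loc[cols],
                           n_perm=10, seed=0)
        np.testing.assert_allclose(res1["t"], res2["t"], atol=1e-9)

    def test_few_perms_warns(self, rng):
        feature, traits, cov = null_trans_cohort(rng, n=30, n_genes=10)
        with pytest.warns(UserWarning):
            trans_assoc(feature, traits, cov, n_perm=5, seed=0)


class TestPathwayScore:
    def test_null_set_score_zero_region(self, rng):
        genes = [f"G{i}" for i in range(100)]
        assoc = pd.DataFrame({"beta": rng.normal(0, 1, 100),
                              "p": rng.uniform(0, 1, 100)}, index=genes)
        res = pathway_score(assoc, {"s": genes[::2]})
        assert res.loc["s", "p"] > 0.001

    def test_planted_up_set(self, rng):
        genes = [f"G{i}" for i in range(200)]
        beta = rng.normal(0, 0.1, 200)
        p = rng.uniform(0.2, 1, 200)
        beta[:20] = np.abs(rng.normal(1, 0.1, 20))
        p[:20] = rng.uniform(1e-8, 1e-4, 20)
        assoc = pd.DataFrame({"beta": beta, "p": p}, index=genes)
        res = pathway_score(assoc, {"up": genes[:20]})
        assert res.loc["up", "direction"] == "up"
        assert res.loc["up", "p_adj"] < 0.05
        assert res.loc["up", "score"] > 0


class TestCisAssoc:
    @staticmethod
    def build_cohort(seed=0, n=60, n_genes=40, planted=6, methyl_planted=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        genes = [f"G{i}" for i in range(n_genes)]
        variations, traits = {}, {
            t: pd.DataFrame(index=genes, columns=samples, dtype=float)
            for t in ["mrna", "protein", "phospho"]
        }
        for gi, g in enumerate(genes):
            lr = rng.normal(0, 1, n)
            baf = rng.normal(0, 1, n)
            me = rng.normal(0, 1, n)
            variations[g] = pd.DataFrame(
                {"cnv_lr": lr, "cnv_baf": baf, "methylation": me}, index=samples)
            base = rng.normal(0, 1, (3, n))
            if gi < planted:
                base += 1.0 * lr
            elif gi < planted + methyl_planted:
                base += 1.0 * me  # positive methylation effect: must be filtered
            for ti, t in enumerate(["mrna", "protein", "phospho"]):
                traits[t].loc[g] = base[ti] + rng.normal(0, 0.4, n)
        return variations, traits

    def test_planted_all_three(self):
        variations, traits = self.build_cohort(seed=1)
        res = cis_assoc(variations, traits, n_perm=20, seed=0)
        for g in [f"G{i}" for i in range(6)]:
            assert res.configuration[(g, "cnv_lr")] == "all_three"

    def test_positive_methylation_filtered_out(self):
        variations, traits = self.build_cohort(seed=2, planted=0, methyl_planted=6)
        res = cis_assoc(variations, traits, n_perm=20, seed=0)
        for g in [f"G{i}" for i in range(6)]:
            assert not res.filters.loc[(g, "methylation"), "passed"]
            assert res.configuration[(g, "methylation")] == "none"

    def test_null_calibration(self):
        n_called, n_total = 0, 0
        for rep in range(3):
            variations, traits = self.build_cohort(seed=50 + rep, planted=0)
            res = cis_assoc(variations, traits, n_perm=20, seed=rep)
            any_call = res.significant.any(axis=1)
            per_gene = any_call.groupby(level="gene").any()
            n_called += int(per_gene.sum())
            n_total += len(per_gene)
        rate = n_called / n_total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_total)

    def test_too_few_genes_errors(self):
        variations, traits = self.build_cohort(n_genes=10)
        with pytest.raises(ValueError):
            cis_assoc(variations, traits)


class TestR2Decomposition:
    def test_orthogonal_variation_near_zero(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        y = pd.Series(rng.normal(0, 1, n))
        design = pd.DataFrame({"v": x})
        dr2 = r2_decomposition(y, design, ["v"])
        assert dr2["v"] < 0.05

    def test_single_predictor_equals_squared_pearson(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        dr2 = r2_decomposition(pd.Series(y), pd.DataFrame({"v": x}), ["v"])
        r = np.corrcoef(x, y)[0, 1]
        assert dr2["v"] == pytest.approx(r ** 2, abs=1e-10)

    def test_matches_two_fit_oracle(self, rng):
        n = 80
        design = pd.DataFrame({
            "v1": rng.normal(0, 1, n),
            "v2": rng.normal(0, 1, n),
            "c": rng.normal(0, 1, n),
        })
        y = design["v1"] * 0.7 - design["v2"] * 0.3 + rng.normal(0, 1, n)

        def r2(X):
            X = np.column_stack([np.ones(n), X])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return 1 - (r @ r) / np.sum((y - y.mean()) ** 2)

        dr2 = r2_decomposition(y, design, ["v1", "v2"])
        full = r2(design.to_numpy())
        assert dr2["v1"] == pytest.approx(full - r2(design[["v2", "c"]].to_numpy()), abs=1e-10)
        assert dr2["v2"] == pytest.approx(full - r2(design[["v1", "c"]].to_numpy()), abs=1e-10)

    def test_collinear_design_errors(self, rng):
        x = rng.normal(0, 1, 50)
        design = pd.DataFrame({"v1": x, "v2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            r2_decomposition(pd.Series(rng.normal(0, 1, 50)), design, ["v1"])


class TestClinicalMultivariate:
    @staticmethod
    def build(seed=0, n=60, n_genes=80, planted=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        clinical = pd.DataFrame({
            "age": rng.normal(60, 10, n),
            "grade": rng.integers(1, 5, n).astype(float),
            "gender": rng.choice(["F", "M"], n),
        }, index=samples)
        Y = rng.normal(0, 1, (n_genes, n))
        Y[:planted] += 0.7 * (clinical["grade"].to_numpy() - 2.5)
        traits = pd.DataFrame(Y, index=[f"G{i}" for i in range(n_genes)],
                              columns=samples)
        return traits, clinical

    def test_null_covariate_few_calls(self):
        traits, clinical = self.build(seed=3)
        res = clinical_multivariate(traits, clinical)
        assert res["counts"]["age"] <= 5

    def test_planted_grade_effect_dominates(self):
        traits, clinical = self.build(seed=4, planted=15)
        res = clinical_multivariate(traits, clinical)
        called = set(traits.index[res["p_adj"]["grade"] < 0.10])
        planted = {f"G{i}" for i in range(15)}
        assert len(called & planted) >= 12
        assert len(called - planted) <= 3

    def test_coefficients_match_ols_oracle(self):
        traits, clinical = self.build(seed=5, n_genes=5)
        res = clinical_multivariate(traits, clinical)
        import statsmodels.api as sm
        X = pd.DataFrame({
            "age": clinical["age"],
            "grade": clinical["grade"],
            "gender_M": (clinical["gender"] == "M").astype(float),
        })
        for g in traits.index:
            fit = sm.OLS(traits.loc[g], sm.add_constant(X)).fit()
            for c in ["age", "grade", "gender_M"]:
                assert res["beta"].loc[g, c] == pytest.approx(fit.params[c], rel=1e-6)
                assert res["p"].loc[g, c] == pytest.approx(fit.pvalues[c], rel=1e-6)

    def test_rank_deficient_lists_aliased(self):
        traits, clinical = self.build(seed=6, n_genes=5)
        clinical["age2"] = clinical["age"] * 2
        with pytest.raises(ValueError, match="age2"):
            clinical_multivariate(traits, clinical)
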