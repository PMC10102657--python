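"""Quantitative-genetic estimators: hand-computed ANOVA, variance
components, parameter identities from the printed trial summary,
correlation decomposition, path coefficients, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germdiv.io_formats import PhenotypeTrial
from germdiv.quantgen import (
    VarianceComponents,
    genetic_params,
    genetic_params_table,
    genotypic_phenotypic_correlations,
    path_analysis,
    rbd_anova,
    trait_cluster,
    trait_pca,
    variance_components,
)
from germdiv.synthetic_data import PhenotypeSimSpec, simulate_rbd_phenotypes


def make_trial(values: np.ndarray, trait: str = "t1") -> PhenotypeTrial:
    g, r = values.shape
    rows = [
        (f"g{i + 1}", f"b{j + 1}", trait, float(values[i, j]))
        for i in range(g)
        for j in range(r)
    ]
    return PhenotypeTrial(pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"]))


class TestAnova:
    def test_hand_computed_sums_of_squares(self, tiny_trial):
        an = rbd_anova(tiny_trial, "t1")
        assert an.ss["genotypes"] == pytest.approx(4.0)
        assert an.ss["blocks"] == pytest.approx(6.0)
        assert an.ss["error"] == pytest.approx(0.0, abs=1e-12)
        assert an.df == {"genotypes": 2, "blocks": 1, "error": 2}

    def test_constant_values_give_zero_ss(self):
        an = rbd_anova(make_trial(np.full((4, 3), 7.0)), "t1")
        assert all(abs(v) < 1e-9 for v in an.ss.values())

    def test_brute_force_oracle_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            y = rng.normal(size=(4, 3))
            an = rbd_anova(make_trial(y), "t1")
            # direct summation oracle over cells
            gm = y.mean()
            ss_g = 3 * ((y.mean(axis=1) - gm) ** 2).sum()
            ss_b = 4 * ((y.mean(axis=0) - gm) ** 2).sum()
            resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + gm
            assert an.ss["genotypes"] == pytest.approx(ss_g)
            assert an.ss["blocks"] == pytest.approx(ss_b)
            assert an.ss["error"] == pytest.approx((resid**2).sum())

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        trial = make_trial(rng.normal(size=(5, 3)))
        an = rbd_anova(trial, "t1")
        fit = ols("value ~ C(genotype) + C(block)", data=trial.records).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert an.ss["genotypes"] == pytest.approx(table.loc["C(genotype)", "sum_sq"])
        assert an.ss["blocks"] == pytest.approx(table.loc["C(block)", "sum_sq"])
        assert an.ss["error"] == pytest.approx(table.loc["Residual", "sum_sq"])

    def test_incomplete_design_rejected(self, tiny_trial):
        records = tiny_trial.records.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rbd_anova(PhenotypeTrial(records), "t1")


class TestVarianceComponents:
    def test_plug_in(self):
        an = rbd_anova(make_trial(np.arange(12.0).reshape(4, 3)), "t1")
        an.ms = {"genotypes": 13.0, "blocks": 1.0, "error": 1.0}
        vc = variance_components(an)
        assert vc.sigma2_g == pytest.approx(4.0)
        assert vc.sigma2_p == pytest.approx(5.0)
        assert not vc.truncated

    @pytest.mark.parametrize("ms_g", [0.5, 1.0])
    def test_truncation_at_zero(self, ms_g):
        an = rbd_anova(make_trial(np.arange(12.0).reshape(4, 3)), "t1")
        an.ms = {"genotypes": ms_g, "blocks": 1.0, "error": 1.0}
        vc = variance_components(an)
        assert vc.sigma2_g == 0.0
        assert vc.truncated == (ms_g < 1.0)


class TestGeneticParams:
    def test_printed_trial_identities(self):
        # plant-height row of the published summary: mean 118.65,
        # PCV 16.80, h2 95.91 reproduce GA 39.38-39.39 and GAM 33.20
        mean, pcv, h2 = 118.65, 16.80, 95.91
        sigma_p = pcv * mean / 100.0
        ga = 2.06 * (h2 / 100.0) * sigma_p
        assert ga == pytest.approx(39.39, abs=0.01)
        assert 100.0 * ga / mean == pytest.approx(33.20, abs=0.01)

    def test_no_error_variance_collapses(self):
        vc = VarianceComponents(4.0, 0.0, 3)
        gp = genetic_params(vc, grand_mean=10.0)
        assert gp.h2 == pytest.approx(100.0)
        assert gp.gcv == pytest.approx(gp.pcv)

    def test_ga_linear_in_k(self):
        vc = VarianceComponents(4.0, 1.0, 3)
        g1 = genetic_params(vc, 10.0, k=1.0)
        g2 = genetic_params(vc, 10.0, k=2.0)
        assert g2.ga == pytest.approx(2 * g1.ga)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            genetic_params(VarianceComponents(1.0, 1.0, 3), 0.0)

    def test_table_gcv_le_pcv(self):
        spec = PhenotypeSimSpec(
            20, 3, [("a", 50.0, 4.0, 1.0), ("b", 10.0, 0.5, 2.0)], seed=9
        )
        table = genetic_params_table(simulate_rbd_phenotypes(spec))
        assert (table.loc["GCV"] <= table.loc["PCV"] + 1e-9).all()
        assert table.loc["GAM"].equals(100 * table.loc["GA"] / table.loc["Mean"])


class TestCorrelations:
    def test_duplicated_trait_correlates_perfectly(self):
        spec = PhenotypeSimSpec(12, 3, [("a", 10.0, 2.0, 0.5)], seed=4)
        trial = simulate_rbd_phenotypes(spec)
        dup = trial.records.assign(trait="b")
        both = PhenotypeTrial(pd.concat([trial.records, dup], ignore_index=True))
        cs = genotypic_phenotypic_correlations(both)
        assert cs.genotypic.loc["a", "b"] == pytest.approx(1.0)
        assert cs.phenotypic.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_error_variance_makes_rg_equal_rp(self):
        rng = np.random.default_rng(0)
        g_effects = rng.normal(size=(10, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]])
        rows = []
        for t, name in enumerate(["a", "b"]):
            for i in range(10):
                for b in range(3):
                    rows.append((f"g{i}", f"b{b}", name, float(g_effects[i, t])))
        trial = PhenotypeTrial(
            pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"])
        )
        cs = genotypic_phenotypic_correlations(trial)
        assert cs.genotypic.loc["a", "b"] == pytest.approx(
            cs.phenotypic.loc["a", "b"], abs=1e-9
        )

    def test_zero_genotypic_variance_reported_missing(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            for b in range(3):
                rows.append((f"g{i}", f"b{b}", "flat", float(b)))  # no genotype signal
                rows.append((f"g{i}", f"b{b}", "var", float(i + rng.normal())))
        trial = PhenotypeTrial(
            pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"])
        )
        cs = genotypic_phenotypic_correlations(trial)
        assert np.isnan(cs.genotypic.loc["flat", "var"])

    def test_genetic_correlation_recovery(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        estimates = []
        for seed in range(12):
            spec = PhenotypeSimSpec(
                200, 3, [("a", 50.0, 4.0, 1.0), ("b", 30.0, 4.0, 1.0)],
                genetic_correlation=corr, seed=seed,
            )
            cs = genotypic_phenotypic_correlations(simulate_rbd_phenotypes(spec))
            estimates.append(cs.genotypic.loc["a", "b"])
        assert np.mean(estimates) == pytest.approx(0.6, abs=0.1)


class TestPathAnalysis:
    def test_single_predictor(self):
        res = path_analysis(np.array([[1.0]]), np.array([0.6]))
        assert res.direct_effects[0] == pytest.approx(0.6)
        assert res.residual_effect == pytest.approx(np.sqrt(1 - 0.36))

    def test_identity_r_returns_r(self):
        r = np.array([0.2, -0.5, 0.7])
        res = path_analysis(np.eye(3), r)
        np.testing.assert_allclose(res.direct_effects, r)

    def test_two_by_two_hand_solution(self):
        res = path_analysis(
            np.array([[1.0, 0.5], [0.5, 1.0]]), np.array([0.6, 0.7])
        )
        np.testing.assert_allclose(res.direct_effects, [1 / 3, 8 / 15], atol=1e-4)
        assert res.residual_effect == pytest.approx(np.sqrt(1 - 0.5733), abs=1e-4)
        # indirect effect of predictor 1 via 2 is r_12 * p_2
        assert res.indirect_effects[0, 1] == pytest.approx(0.5 * 8 / 15)

    def test_singular_matrix_names_collinear_pair(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="collinear"):
            path_analysis(R, np.array([0.5, 0.5]), predictors=["x", "y"])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        x = rng.normal(size=(60, n))
        y = x @ rng.normal(size=n) + rng.normal(size=60)
        full = np.corrcoef(np.column_stack([x, y]), rowvar=False)
        R, r = full[:n, :n], full[:n, n]
        res = path_analysis(R, r)
        # p_i + sum_{j != i} r_ij p_j = r_iy exactly
        np.testing.assert_allclose(R @ res.direct_effects, r, atol=1e-10)


class TestClusteringAndPca:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0.0, 0.1, size=(10, 3))
        blob2 = rng.normal(8.0, 0.1, size=(10, 3))
        means = pd.DataFrame(
            np.vstack([blob1, blob2]),
            index=[f"g{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        assignments, cluster_means, _ = trait_cluster(means, 2)
        labels = assignments.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        assert cluster_means.shape == (2, 3)

    def test_singleton_clusters_equal_genotype_means(self):
        rng = np.random.default_rng(2)
        means = pd.DataFrame(
            rng.normal(size=(5, 2)), index=[f"g{i}" for i in range(5)], columns=["a", "b"]
        )
        assignments, cluster_means, _ = trait_cluster(means, 5)
        assert assignments.nunique() == 5
        for g, c in assignments.items():
            np.testing.assert_allclose(
                cluster_means.loc[f"Cluster-{c}"].to_numpy(), means.loc[g].to_numpy()
            )

    def test_duplicated_genotypes_merge_at_height_zero(self):
        means = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]],
            index=["g1", "g2", "g3"],
            columns=["a", "b"],
        )
        _, _, tree = trait_cluster(means, 2)
        paths = tree.path_lengths()
        assert paths[("g1", "g2")] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_dropped_with_warning(self):
        means = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}, index=["g1", "g2", "g3"]
        )
        with pytest.warns(UserWarning, match="constant"):
            trait_cluster(means, 2)

    def test_pca_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 10)
        means = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"g{i}" for i in range(10)])
        eigvals, _, _, percent = trait_pca(means)
        np.testing.assert_allclose(eigvals, [2.0, 0.0], atol=1e-10)
        assert percent[0] == pytest.approx(100.0)

    def test_pca_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(7)
        means = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=["a", "b", "c"],
            index=[f"g{i}" for i in range(40)],
        )
        eigvals, loadings, scores, _ = trait_pca(means)
        corr = np.corrcoef((means - means.mean()) / means.std(ddof=1), rowvar=False)
        roots = np.sort(np.roots(np.poly(corr)))[::-1]
        np.testing.assert_allclose(eigvals, roots.real, atol=1e-8)
        assert eigvals.sum() == pytest.approx(3.0)
        # scores reproduce the standardized data in the loading basis
        z = ((means - means.mean()) / means.std(ddof=1)).to_numpy()
        np.testing.assert_allclose(scores.to_numpy() @ loadings.to_numpy().T, z, atol=1e-8)
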