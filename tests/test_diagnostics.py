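import numpy as np
import pytest

import allomkit as ak
from allomkit.data_model_io import DataError
from conftest import make_dataset


class TestObsVsPred:
    def test_identity_line(self):
        reg = ak.obs_vs_pred([5.0, 10.0, 15.0], [5.0, 10.0, 15.0])
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.slope == pytest.approx(1.0)
        assert reg.residual_ms == pytest.approx(0.0, abs=1e-20)

    def test_doubling(self):
        reg = ak.obs_vs_pred([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pred_degenerate(self):
        with pytest.raises(DataError, match="constant"):
            ak.obs_vs_pred([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestGraybill:
    def test_perfect_agreement(self):
        F, p = ak.graybill_test(ak.obs_vs_pred([5.0, 10, 15], [5.0, 10, 15]))
        assert F == 0.0 and p == 1.0

    def test_pure_offset_rejected(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(5, 40, 50)
        obs = pred + 10.0 + rng.normal(0, 0.5, 50)
        F, p = ak.graybill_test(ak.obs_vs_pred(obs, pred))
        assert p < 1e-3 and F > 80

    def test_unit_invariance(self):
        """F is unchanged when obs and pred are both rescaled (cm vs m)."""
        rng = np.random.default_rng(4)
        pred = rng.uniform(5, 40, 30)
        obs = 1.1 * pred + rng.normal(0, 2, 30)
        F1, _ = ak.graybill_test(ak.obs_vs_pred(obs, pred))
        F2, _ = ak.graybill_test(ak.obs_vs_pred(100 * obs, 100 * pred))
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_equals_bias_plus_consistency_over_2mse(self):
        """Graybill's joint F equals (SS_bias + SS_consistency)/(2 MSE):
        the joint test and the per-component decomposition reconcile."""
        rng = np.random.default_rng(5)
        pred = rng.uniform(5, 40, 40)
        obs = 2 + 0.9 * pred + rng.normal(0, 2, 40)
        reg = ak.obs_vs_pred(obs, pred)
        F, _ = ak.graybill_test(reg)
        th = ak.theil_decomposition(obs, pred)
        assert F == pytest.approx(
            (th.ss_bias + th.ss_consistency) / (2 * reg.residual_ms), rel=1e-9)


class TestTheil:
    def test_identical_series_all_zero(self):
        th = ak.theil_decomposition(np.arange(1.0, 11), np.arange(1.0, 11))
        assert th.ss_total_lack_of_fit == pytest.approx(0.0, abs=1e-18)
        assert th.ss_bias == pytest.approx(0.0, abs=1e-18)
        assert th.ss_consistency == pytest.approx(0.0, abs=1e-18)
        assert th.ss_regression_lack_of_fit == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset_is_pure_bias(self):
        pred = np.linspace(5, 40, 12)
        obs = pred + 3.0
        th = ak.theil_decomposition(obs, pred)
        assert th.ss_bias == pytest.approx(12 * 9.0)
        assert th.ss_consistency == pytest.approx(0.0, abs=1e-16)
        assert th.ss_regression_lack_of_fit == pytest.approx(0.0, abs=1e-16)

    def test_components_sum_to_total(self):
        """Brute-force summation oracle: components add up to Σ(obs-pred)²."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            pred = rng.uniform(2, 50, 20)
            obs = pred * rng.uniform(0.8, 1.2) + rng.normal(0, 3, 20)
            th = ak.theil_decomposition(obs, pred)
            total = float(np.sum((obs - pred) ** 2))
            parts = th.ss_bias + th.ss_consistency + th.ss_regression_lack_of_fit
            assert parts == pytest.approx(total, rel=1e-9)
            assert min(th.ss_bias, th.ss_consistency,
                       th.ss_regression_lack_of_fit) >= 0.0


class TestSpeciesMixed:
    def test_r2c_equals_r2m_without_species_variance(self):
        rng = np.random.default_rng(7)
        D = rng.uniform(5, 60, 300)
        H = -2 + 8 * np.log(D) + rng.normal(0, 3, 300)
        ds = make_dataset(D, H)  # 5 species labels, no species effect
        res = ak.fit_species_mixed(ds, "log_linear")
        assert res.r2_conditional >= res.r2_marginal
        assert res.r2_conditional - res.r2_marginal < 0.02

    def test_variance_components_recovered(self):
        """Simulation oracle: species intercept SD 2, residual SD 4,
        slope 8 on lnD; REML recovers both variances within 20% (mean
        over seeds, n=1500, 30 species)."""
        sp_var, res_var = [], []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            n, n_sp = 1500, 30
            sp = rng.integers(n_sp, size=n)
            intercepts = rng.normal(0, 2.0, n_sp)
            D = rng.uniform(3, 80, n)
            H = 1.0 + 8.0 * np.log(D) + intercepts[sp] + rng.normal(0, 4.0, n)
            recs = [ak.TreeRecord("P1", f"t{i}", "F", "G", f"sp{sp[i]}",
                                  float(D[i]), "terra_firme", float(max(H[i], 1.2)))
                    for i in range(n)]
            res = ak.fit_species_mixed(ak.ForestDataset(recs, {"P1": 1.0}))
            sp_var.append(res.species_variance)
            res_var.append(res.residual_variance)
        assert np.mean(sp_var) == pytest.approx(4.0, rel=0.2)
        assert np.mean(res_var) == pytest.approx(16.0, rel=0.2)

    def test_single_species_errors(self):
        D = np.linspace(5, 50, 10)
        recs = [ak.TreeRecord("P1", f"t{i}", "F", "G", "onesp", float(d),
                              "terra_firme", float(5 + d / 2))
                for i, d in enumerate(D)]
        with pytest.raises(DataError, match="fixed-effects"):
            ak.fit_species_mixed(ak.ForestDataset(recs, {"P1": 1.0}))

    def test_pooled_forests_increase_species_share(self, tf_stand, vz_stand):
        """Disjoint species pools with different height laws: the species
        random effect explains more variance in the pooled data than
        within either forest."""
        tf, _ = tf_stand
        vz, _ = vz_stand
        pooled = ak.ForestDataset(tf.records + vz.records,
                                  {**tf.plot_areas, **vz.plot_areas})
        gap_tf = ak.fit_species_mixed(tf)
        gap_vz = ak.fit_species_mixed(vz)
        gap_pool = ak.fit_species_mixed(pooled)
        delta_pool = gap_pool.r2_conditional - gap_pool.r2_marginal
        assert delta_pool > gap_tf.r2_conditional - gap_tf.r2_marginal
        assert delta_pool > gap_vz.r2_conditional - gap_vz.r2_marginal


class TestTaxonMaxima:
    def test_maxima_are_per_trait(self):
        recs = [
            ak.TreeRecord("P1", "a", "F", "G", "x", 10, "varzea", height=12.0),
            ak.TreeRecord("P1", "b", "F", "G", "x", 20, "varzea", height=9.0),
            ak.TreeRecord("P1", "c", "F", "G", "indet", 99, "varzea", height=40.0),
        ]
        out = ak.taxon_maxima(ak.ForestDataset(recs))
        assert list(out.index) == ["G x"]
        assert out.loc["G x", "dmax"] == 20.0
        assert out.loc["G x", "hmax"] == 12.0

    def test_single_tree_species(self):
        recs = [ak.TreeRecord("P1", "a", "F", "G", "y", 33, "varzea", height=21.0),
                ak.TreeRecord("P1", "b", "F", "G", "z", 12, "varzea", height=8.0)]
        out = ak.taxon_maxima(ak.ForestDataset(recs))
        assert out.loc["G y", "dmax"] == 33.0 and out.loc["G y", "hmax"] == 21.0


@pytest.fixture(scope="module")
def maxima():
    rng = np.random.default_rng(8)
    n = 30
    dmax = rng.uniform(10, 120, n)
    hmax = np.exp(0.5 + 1.1 * np.log(dmax) - 0.09 * np.log(dmax) ** 2) \
        + rng.normal(0, 3, n)
    import pandas as pd
    return pd.DataFrame({"dmax": dmax, "hmax": np.maximum(hmax, 2.0)},
                        index=[f"sp{i}" for i in range(n)])


class TestPGLS:

    def test_identity_covariance_reproduces_ols(self, maxima):
        import statsmodels.api as sm
        n = len(maxima)
        res = ak.pgls_fit(maxima, covariance=np.eye(n))
        lnD = np.log(maxima["dmax"].to_numpy())
        X = np.column_stack([np.ones(n), lnD, lnD**2])
        ols = sm.OLS(maxima["hmax"].to_numpy(), X).fit()
        np.testing.assert_allclose(res.coefficients, ols.params, rtol=1e-8)

    def test_star_phylogeny_reproduces_ols(self, maxima):
        """Equal independent tips (star tree) carry no phylogenetic
        information: PGLS must equal OLS."""
        import dendropy
        taxa = list(maxima.index)
        newick = "(" + ",".join(f"{t}:1.0" for t in taxa) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        res_tree = ak.pgls_fit(maxima, tree=tree)
        res_id = ak.pgls_fit(maxima, covariance=np.eye(len(taxa)))
        np.testing.assert_allclose(res_tree.coefficients, res_id.coefficients,
                                   rtol=1e-8)

    def test_missing_taxa_listed(self, maxima):
        tree = ak.generate_phylogeny(list(maxima.index)[:-2], seed=1)
        with pytest.raises(DataError, match="sp2"):
            ak.pgls_fit(maxima, tree=tree)

    def test_brownian_covariance_shared_paths(self):
        import dendropy
        tree = dendropy.Tree.get(data="((a:1.0,b:1.0):2.0,c:3.0);",
                                 schema="newick")
        C = ak.phylo_covariance(tree, ["a", "b", "c"])
        np.testing.assert_allclose(C, [[3, 2, 0], [2, 3, 0], [0, 0, 3]])

    def test_pagel_lambda_near_one_for_brownian_trait(self):
        """Brownian-simulated traits on a Yule tree show strong signal."""
        species = [f"s{i}" for i in range(50)]
        tree = ak.generate_phylogeny(species, seed=2)
        C = ak.phylo_covariance(tree, species)
        rng = np.random.default_rng(9)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(50))
        lams = []
        import pandas as pd
        for _ in range(5):
            trait = L @ rng.standard_normal(50)
            dmax = np.exp(rng.uniform(2.5, 4.5, 50))
            hmax = 10 + 2 * trait
            maxima = pd.DataFrame({"dmax": dmax, "hmax": hmax}, index=species)
            lams.append(ak.pagel_lambda(maxima, tree))
        assert np.mean(lams) > 0.8
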