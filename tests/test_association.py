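"""Eigengenes, kME, gene significance, trait adjustment, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from coexnet.association import (
    adjust_trait,
    benjamini_hochberg,
    eigengene_set,
    gene_significance,
    module_eigengene,
    module_membership,
    module_trait_correlation,
)
from coexnet.io import ExpressionMatrix, TraitMeta, TraitTable
from coexnet.simulate import SimulationConfig, TraitSpec, generate_dataset

from conftest import make_expr


def bh_oracle(p):
    """Definitional min-over-tails step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [p[j] * m / (list(order).index(j) + 1) for j in order[rank_idx:]]
        q[i] = min(1.0, min(tail))
    return q


class TestModuleEigengene:
    def test_rank_one_module(self, rng):
        profile = rng.standard_normal(15)
        z = (profile - profile.mean()) / profile.std()
        expr = make_expr(np.tile(z, (5, 1)) * np.array([1, 2, 3, 4, 5])[:, None])
        eig = module_eigengene(expr, list(expr.feature_ids))
        assert eig.variance_explained == pytest.approx(1.0)
        r = np.corrcoef(eig.values, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_unit_norm_zero_mean_and_sign(self, rng):
        expr = make_expr(rng.standard_normal((8, 20)))
        eig = module_eigengene(expr, list(expr.feature_ids))
        assert np.linalg.norm(eig.values) == pytest.approx(1.0)
        assert eig.values.mean() == pytest.approx(0.0, abs=1e-12)
        x = expr.data.to_numpy()
        cors = [np.corrcoef(row, eig.values)[0, 1] for row in x]
        assert np.mean(cors) > 0  # sign convention

    def test_noise_module_variance_explained_sanity(self):
        # uncorrelated genes: leading-PC share ~ 1/m, inflated by the usual
        # largest-eigenvalue bias; must sit between 1/m and 2/m for n >> m
        m, n = 10, 200
        ve = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            expr = make_expr(rng.standard_normal((m, n)))
            ve.append(module_eigengene(expr, list(expr.feature_ids)).variance_explained)
        assert 1 / m < np.mean(ve) < 2 / m

    def test_noiseless_factor_module_tracks_factor_positively(self):
        cfg = SimulationConfig(
            n_genes=20, module_sizes=[20], within_module_cor=1.0, n_samples=12, seed=3
        )
        expr, _, truth = generate_dataset(cfg)
        eig = module_eigengene(expr, list(expr.feature_ids))
        r = np.corrcoef(eig.values, truth.factors.loc[1].to_numpy())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_gene_order_invariance_up_to_sign_convention(self, rng):
        expr = make_expr(rng.standard_normal((12, 18)))
        genes = list(expr.feature_ids)
        e1 = module_eigengene(expr, genes)
        e2 = module_eigengene(expr, genes[::-1])
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-10)

    def test_too_few_genes(self, small_expr):
        with pytest.raises(ValueError):
            module_eigengene(small_expr, [small_expr.feature_ids[0]])


class TestModuleMembership:
    def test_kme_extremes_and_oracle(self, rng):
        expr = make_expr(rng.standard_normal((30, 20)))
        labels = pd.Series([1] * 15 + [2] * 15, index=expr.feature_ids)
        eigs = eigengene_set(expr, labels)
        kme = module_membership(expr, eigs)
        x = expr.data.to_numpy()
        for gi, g in enumerate(expr.feature_ids):
            for m, eig in eigs.eigengenes.items():
                expected = np.corrcoef(x[gi], eig.values)[0, 1]
                assert kme.loc[g, m] == pytest.approx(expected, abs=1e-12)

    def test_gene_equal_to_eigengene(self, rng):
        expr0 = make_expr(rng.standard_normal((10, 16)))
        labels = pd.Series([1] * 10, index=expr0.feature_ids)
        eigs = eigengene_set(expr0, labels)
        data = expr0.data.copy()
        data.loc["echo"] = eigs.eigengenes[1].values
        expr = ExpressionMatrix(data)
        kme = module_membership(expr, eigs)
        assert kme.loc["echo", 1] == pytest.approx(1.0)


class TestGeneSignificance:
    def test_trait_equal_to_gene(self, small_expr):
        trait = small_expr.data.iloc[0]
        gs = gene_significance(small_expr, trait)
        assert gs.iloc[0] == pytest.approx(1.0)

    def test_constant_trait_errors(self, small_expr):
        with pytest.raises(ValueError):
            gene_significance(
                small_expr, pd.Series(1.0, index=small_expr.sample_ids)
            )

    def test_planted_trait_separates_module_from_background(self):
        wins = 0
        for seed in range(100):
            cfg = SimulationConfig(
                n_genes=120, module_sizes=[40], within_module_cor=0.5,
                trait_specs=[TraitSpec("t", effects=[(1, 1.0)], noise_sd=0.5)],
                seed=seed,
            )
            expr, traits, truth = generate_dataset(cfg)
            gs = gene_significance(expr, pd.to_numeric(traits.data["t"]))
            in_mod = gs[truth.planted_labels == 1].mean()
            in_bg = gs[truth.planted_labels == 0].mean()
            wins += int(in_mod > in_bg)
        assert wins >= 95


class TestAdjustTrait:
    def test_trait_linear_in_covariate_residuals_zero(self):
        idx = [f"S{i}" for i in range(10)]
        sex = pd.DataFrame({"sex": [0, 1] * 5}, index=idx, dtype=float)
        trait = pd.Series([2.0 * s + 1 for s in sex.sex], index=idx)
        res = adjust_trait(trait, sex)
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_covariate_keeps_centered_trait(self):
        idx = [f"S{i}" for i in range(8)]
        cov = pd.DataFrame({"c": [1, -1] * 4}, index=idx, dtype=float)
        trait = pd.Series([1.0, 1, 2, 2, 3, 3, 4, 4], index=idx)
        res = adjust_trait(trait, cov)
        np.testing.assert_allclose(
            res.to_numpy(), (trait - trait.mean()).to_numpy(), atol=1e-10
        )

    def test_missing_values_propagate(self):
        idx = [f"S{i}" for i in range(6)]
        cov = pd.DataFrame({"c": [0.0, 1, 0, 1, 0, 1]}, index=idx)
        trait = pd.Series([1.0, np.nan, 3, 4, 5, 6], index=idx)
        res = adjust_trait(trait, cov)
        assert np.isnan(res["S1"]) and res.notna().sum() == 5

    def test_rank_deficient_design_errors(self):
        idx = [f"S{i}" for i in range(6)]
        cov = pd.DataFrame({"a": [1.0] * 6, "b": [2.0] * 6}, index=idx)
        with pytest.raises(ValueError):
            adjust_trait(pd.Series(np.arange(6.0), index=idx), cov)

    def test_partial_correlation_recovery(self):
        # trait = 2*sex + f + noise: residualizing on sex must recover the
        # f-component correlation within simulation error
        cors_adj, cors_target = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 26
            sex = rng.integers(0, 2, n).astype(float)
            f = rng.standard_normal(n)
            noise = 0.5 * rng.standard_normal(n)
            trait = pd.Series(2 * sex + f + noise, index=range(n))
            res = adjust_trait(trait, pd.DataFrame({"sex": sex}, index=range(n)))
            cors_adj.append(np.corrcoef(res, f)[0, 1])
            cors_target.append(np.corrcoef(f + noise, f)[0, 1])
        assert np.mean(cors_adj) == pytest.approx(np.mean(cors_target), abs=0.02)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.005, 0.04, 0.03])),
            [0.015, 0.04, 0.04],
        )

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(benjamini_hochberg(np.full(7, 0.2)), 0.2)
        np.testing.assert_allclose(benjamini_hochberg(np.array([0.3])), [0.3])

    def test_matches_definitional_oracle_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            q = benjamini_hochberg(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_never_below_raw_and_capped(self, rng):
        for _ in range(100):
            p = rng.random(25)
            q = benjamini_hochberg(p)
            assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.2]))


class TestModuleTraitCorrelation:
    def _fixture(self, seed=0, effect=1.0, noise=0.5):
        cfg = SimulationConfig(
            n_genes=200, module_sizes=[40, 40], within_module_cor=0.8,
            trait_specs=[
                TraitSpec("hit", effects=[(1, effect)], noise_sd=noise),
                TraitSpec("null", effects=[], noise_sd=1.0),
            ],
            seed=seed,
        )
        expr, traits, truth = generate_dataset(cfg)
        eigs = eigengene_set(expr, truth.planted_labels)
        return expr, traits, truth, eigs

    def test_trait_equal_to_eigengene(self):
        expr, traits, truth, eigs = self._fixture()
        tdf = traits.data.copy()
        tdf["echo"] = eigs.eigengenes[1].values
        meta = dict(traits.meta)
        meta["echo"] = TraitMeta(kind="quantitative")
        res = module_trait_correlation(eigs, TraitTable(tdf, meta))
        row = res.table[(res.table.trait == "echo") & (res.table.module == 1)]
        assert row.r.iloc[0] == pytest.approx(1.0)
        assert row.p.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_effect_flagged_significant(self):
        expr, traits, truth, eigs = self._fixture()
        res = module_trait_correlation(eigs, traits)
        hit = res.table[(res.table.trait == "hit") & (res.table.module == 1)]
        assert hit.p_adj.iloc[0] < 0.05
        assert res.table.p_adj.ge(res.table.p - 1e-15).all()

    def test_zero_correlation_p_one(self):
        expr, traits, truth, eigs = self._fixture()
        e = eigs.eigengenes[1].values.copy()
        # project a random trait off the eigengene; since the eigengene has
        # zero mean, raw orthogonality implies exactly zero Pearson r
        v = np.random.default_rng(9).standard_normal(e.size)
        v -= (v @ e) / (e @ e) * e
        tdf = traits.data.copy()
        tdf["orth"] = v + 1.0
        meta = dict(traits.meta)
        meta["orth"] = TraitMeta(kind="quantitative")
        res = module_trait_correlation(eigs, TraitTable(tdf, meta))
        row = res.table[(res.table.trait == "orth") & (res.table.module == 1)]
        assert abs(row.r.iloc[0]) < 1e-8
        assert row.p.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_covariate_adjustment_provenance_recorded(self):
        cfg = SimulationConfig(
            n_genes=100, module_sizes=[30], within_module_cor=0.8,
            trait_specs=[TraitSpec("t", effects=[(1, 0.8)], sex_effect=2.0)],
            seed=4,
        )
        expr, traits, truth = generate_dataset(cfg)
        eigs = eigengene_set(expr, truth.planted_labels)
        res = module_trait_correlation(eigs, traits)
        row = res.table[res.table.trait == "t"]
        assert row.covariates_adjusted.iloc[0] == "sex"

    def test_per_trait_family_option(self):
        expr, traits, truth, eigs = self._fixture()
        res = module_trait_correlation(eigs, traits, bh_family="per_trait")
        for trait in res.table.trait.unique():
            sub = res.table[res.table.trait == trait]
            np.testing.assert_allclose(
                sub.p_adj.to_numpy(), benjamini_hochberg(sub.p.to_numpy()), atol=1e-12
            )

    def test_estimated_r_unbiased_on_planted_effect(self):
        # population cor(trait, factor) = 0.75; estimated module-trait r
        # averaged over replicates must match within Monte-Carlo error
        rho = 0.75
        rs = []
        for seed in range(500):
            cfg = SimulationConfig(
                n_genes=30, module_sizes=[30], within_module_cor=0.9,
                trait_specs=[
                    TraitSpec("t", effects=[(1, rho)], noise_sd=float(np.sqrt(1 - rho**2)))
                ],
                seed=seed,
            )
            expr, traits, truth = generate_dataset(cfg)
            eigs = eigengene_set(expr, truth.planted_labels)
            res = module_trait_correlation(eigs, traits)
            rs.append(res.table[res.table.trait == "t"].r.iloc[0])
        # |r| attenuates O(1/n); at n = 26 the mean estimate stays within a few
        # percent of the population value
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)
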