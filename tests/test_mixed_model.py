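"""Animal-model REML: oracle equivalence, ascent, recovery, parameters, BLUP."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (brute_force_reml, numeric_gradient,
                      random_animal_dataset)

from f2quant.mixed_model import (DesignSpaceError, GeneticParameters,
                                 REMLOptions, build_design, correlations,
                                 heritability, predict_ebv, reml_bivariate,
                                 reml_univariate, screen_fixed_effects,
                                 select_heritability)
from f2quant.mixed_model.reml import (BivariateComponents, VarianceComponents,
                                      _UniState)
from f2quant.pedigree import (RelationshipMatrix, additive_relationship_matrix,
                              pedigree_from_records)
from f2quant.simulate import simulate_phenotypes
from f2quant.traits import TraitSpec

FAST = REMLOptions(compute_ebv=False, compute_pev=False)


def _toy_system(rng, n=25, h2=0.5):
    """Small dataset wrapped in a synthetic founder 'pedigree' carrier."""
    y, X, K = random_animal_dataset(rng, n_animals=n, h2=h2)
    return y, X, K


def _fit_direct(y, X, K, opts=FAST):
    """Run the univariate engine on raw arrays via a founder pedigree shim."""
    n = len(y)
    ped = pedigree_from_records([(f"I{i}", "0", "0") for i in range(n)])
    from f2quant.mixed_model.design import DesignSystem, TraitDesign
    td = TraitDesign(trait="t", y=y, X=X, x_names=[f"b{j}" for j in
                                                   range(X.shape[1])],
                     animal_idx=np.arange(n), n_dropped=0)
    ds = DesignSystem(traits=[td], ped=ped)
    rm = RelationshipMatrix(ids=ped.ids, A=K)
    return reml_univariate(ds, rm, opts)


class TestBuildDesign:
    def _table(self, aped, table):
        return table

    def test_column_count_for_no_length_trait(self, analysis_population):
        aped, rm, table = analysis_population
        ds = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        # intercept + sex + 2 SOB contrasts + age
        assert ds.traits[0].X.shape[1] == 5
        assert ds.traits[0].x_names == [
            "intercept", "sex[M]", "sob[2.0]", "sob[3.0]", "age_2m"]

    def test_missing_covariate_record_dropped(self, analysis_population):
        aped, rm, table = analysis_population
        work = table.copy()
        first = work.index[work["trait"].notna()][0]
        work.loc[first, "age_2m"] = np.nan
        ds = build_design(work, TraitSpec("trait", age_column="age_2m"), aped)
        full = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        assert len(ds.traits[0].y) == len(full.traits[0].y) - 1

    def test_pair_with_disjoint_records_builds_and_flags(self, analysis_population):
        aped, rm, table = analysis_population
        work = table.copy()
        obs = work.index[work["trait"].notna()]
        half = len(obs) // 2
        work["t2"] = work["trait"]
        work.loc[obs[:half], "t2"] = np.nan
        work.loc[obs[half:], "trait"] = np.nan
        specs = [TraitSpec("trait", age_column="age_2m"),
                 TraitSpec("t2", age_column="age_2m")]
        ds = build_design(work, specs, aped)
        assert len(ds.overlap) == 0
        with pytest.warns(UserWarning, match="residual covariance fixed"):
            bc, _ = reml_bivariate(ds, rm, FAST)
        assert bc.R[0, 1] == 0.0 and not bc.residual_cov_estimated

    def test_empty_records_error(self, analysis_population):
        aped, rm, table = analysis_population
        work = table.copy()
        work["trait"] = np.nan
        with pytest.raises(DesignSpaceError):
            build_design(work, TraitSpec("trait", age_column="age_2m"), aped)


class TestScreening:
    def test_null_factor_type_I_error_rate(self):
        rng = np.random.default_rng(0)
        n, reps, hits = 120, 400, 0
        for _ in range(reps):
            tab = pd.DataFrame({
                "y": rng.standard_normal(n),
                "g": rng.choice(["a", "b", "c"], size=n)})
            res = screen_fixed_effects(tab, TraitSpec("y", fixed_factors=(),
                                                      use_age=False), ["g"])
            hits += res[0].significant
        rate = hits / reps
        assert 0.02 < rate < 0.09  # nominal 0.05

    def test_one_sd_effect_detected_at_design_size(self):
        rng = np.random.default_rng(1)
        n, reps, hits = 454, 100, 0
        for _ in range(reps):
            g = rng.choice([0, 1], size=n)
            tab = pd.DataFrame({"y": rng.standard_normal(n) + 1.0 * g,
                                "g": g.astype(str)})
            res = screen_fixed_effects(tab, TraitSpec("y", fixed_factors=(),
                                                      use_age=False), ["g"])
            hits += res[0].significant
        assert hits >= 99

    def test_single_level_factor_errors(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        with pytest.raises(DesignSpaceError, match="single level"):
            screen_fixed_effects(tab, TraitSpec("y", fixed_factors=(),
                                                use_age=False), ["g"])

    def test_aliased_effects_named(self):
        tab = pd.DataFrame({"y": [1.0, 2, 3, 4], "g": ["a", "a", "b", "b"],
                            "h": ["x", "x", "y", "y"]})
        with pytest.raises(DesignSpaceError, match="aliased"):
            screen_fixed_effects(tab, TraitSpec("y", fixed_factors=(),
                                                use_age=False), ["g", "h"])

    def test_partial_f_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(2)
        n = 80
        tab = pd.DataFrame({
            "y": rng.standard_normal(n),
            "g": rng.choice(["a", "b", "c"], size=n),
            "x": rng.standard_normal(n)})
        res = screen_fixed_effects(
            tab, TraitSpec("y", fixed_factors=(), use_age=False), ["g"],
            covariates=["x"])
        model = ols("y ~ C(g) + x", data=tab).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        ours = {r.effect: r for r in res}
        assert ours["g"].f_statistic == pytest.approx(anova.loc["C(g)", "F"],
                                                      rel=1e-8)
        assert ours["x"].p_value == pytest.approx(
            anova.loc["x", "PR(>F)"], rel=1e-8)


class TestUnivariateREML:
    def test_matches_brute_force_surface_on_toy_data(self):
        rng = np.random.default_rng(21)
        y, X, K = _toy_system(rng, n=25)
        vc, _ = _fit_direct(y, X, K)
        va, ve = brute_force_reml(y, X, K)
        assert vc.sigma2_a == pytest.approx(va, abs=1e-4)
        assert vc.sigma2_e == pytest.approx(ve, abs=1e-4)

    def test_em_iterations_never_decrease_loglik(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            y, X, K = _toy_system(rng, n=int(rng.integers(15, 40)),
                                  h2=float(rng.uniform(0.05, 0.95)))
            d, U = np.linalg.eigh(K)
            d = np.clip(d, 0, None)
            ys, Xs = U.T @ y, U.T @ X
            varp = float(np.var(y, ddof=1))
            theta = np.array([0.5 * varp, 0.5 * varp])
            last = -np.inf
            for _i in range(15):
                st = _UniState(theta, d, ys, Xs)
                assert st.loglik >= last - 1e-9
                last = st.loglik
                n = len(y)
                theta = np.maximum(theta + 2 * theta**2 / n * st.grad, 1e-10)

    def test_zero_heritability_data_hits_variance_floor(self):
        rng = np.random.default_rng(4)
        y, X, K = _toy_system(rng, n=60, h2=0.0)
        vc, _ = _fit_direct(y, X, K)
        h2, _se = heritability(vc)
        assert vc.boundary
        assert h2 < 0.02

    def test_record_permutation_invariance(self, analysis_population):
        aped, rm, table = analysis_population
        spec = TraitSpec("trait", age_column="age_2m")
        ds1 = build_design(table, spec, aped)
        shuffled = table.sample(frac=1.0, random_state=0)
        ds2 = build_design(shuffled, spec, aped)
        vc1, _ = reml_univariate(ds1, rm, FAST)
        vc2, _ = reml_univariate(ds2, rm, FAST)
        assert abs(vc1.sigma2_a - vc2.sigma2_a) < 1e-8
        assert abs(vc1.loglik - vc2.loglik) < 1e-8

    def test_design_scale_fit_recovers_h2(self, analysis_population):
        aped, rm, table = analysis_population
        ds = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        vc, _ = reml_univariate(ds, rm, FAST)
        h2, se = heritability(vc)
        assert vc.converged
        assert h2 == pytest.approx(0.5, abs=3 * se)
        assert 0.05 < se < 0.25


class TestBivariateREML:
    def test_same_trait_twice_gives_rg_near_one(self, analysis_population):
        aped, rm, table = analysis_population
        rng = np.random.default_rng(5)
        work = table.copy()
        noise = rng.normal(scale=0.3, size=len(work))
        work["t2"] = work["trait"] + noise
        specs = [TraitSpec("trait", age_column="age_2m"),
                 TraitSpec("t2", age_column="age_2m")]
        bc, _ = reml_bivariate(build_design(work, specs, aped), rm, FAST)
        (rg, _), _ = correlations(bc)
        assert rg > 0.99

    def test_independent_traits_recover_null_rg(self, design_population):
        from f2quant.pedigree import prune_to_phenotyped
        from f2quant.simulate import two_trait_architecture
        ped, cov = design_population
        arch = two_trait_architecture(0.5, 0.5, 0.0, re=0.0)
        rgs = []
        for s in range(20):
            tab = simulate_phenotypes(ped, cov, arch, seed=200 + s)
            aped = prune_to_phenotyped(
                ped, tab.loc[tab.retained.astype(bool), "animal"])
            rm = additive_relationship_matrix(aped)
            specs = [TraitSpec("trait1", age_column="age_2m"),
                     TraitSpec("trait2", age_column="age_2m")]
            bc, _ = reml_bivariate(build_design(tab, specs, aped), rm, FAST)
            (rg, _), _ = correlations(bc)
            rgs.append(rg)
        # per-replicate SD of the null rg estimate is ~0.28 at this design
        # size, so the mean of 20 replicates has SE ~0.06
        assert abs(np.mean(rgs)) < 0.15

    def test_dense_and_fast_paths_agree(self, design_population):
        # complete bivariate records with an interior genetic correlation:
        # the rotated per-block engine and the dense-matrix engine must find
        # the same optimum
        from f2quant.pedigree import prune_to_phenotyped
        from f2quant.simulate import two_trait_architecture
        ped, cov = design_population
        arch = two_trait_architecture(0.5, 0.5, 0.7, re=0.3)
        table = simulate_phenotypes(ped, cov, arch, seed=77)
        aped = prune_to_phenotyped(
            ped, table.loc[table.retained.astype(bool), "animal"])
        rm = additive_relationship_matrix(aped)
        specs = [TraitSpec("trait1", age_column="age_2m"),
                 TraitSpec("trait2", age_column="age_2m")]
        ds = build_design(table, specs, aped)
        bc_fast, _ = reml_bivariate(ds, rm, FAST)
        from f2quant.mixed_model.reml import _bivariate_dense
        (theta, st, _tr, conv), _fl = _bivariate_dense(
            ds.traits[0], ds.traits[1], rm.A, FAST, True)
        assert conv and bc_fast.converged
        assert np.allclose(bc_fast.theta, theta, atol=2e-3)
        assert bc_fast.loglik == pytest.approx(st.loglik, abs=1e-4)


class TestDerivedParameters:
    def test_heritability_point_values(self):
        vc = VarianceComponents(0.57, 0.43, np.eye(2) * 1e-4, 0.0, True,
                                False, [])
        h2, se = heritability(vc)
        assert h2 == pytest.approx(0.57)
        vc2 = VarianceComponents(1.0, 1.0, np.eye(2) * 1e-4, 0.0, True,
                                 False, [])
        assert heritability(vc2)[0] == pytest.approx(0.5)

    def test_h2_se_matches_numeric_propagation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, e = rng.uniform(0.1, 2.0, size=2)
            M = rng.standard_normal((2, 2)) * 0.05
            cov = M @ M.T + 1e-4 * np.eye(2)
            vc = VarianceComponents(a, e, cov, 0.0, True, False, [])
            _, se = heritability(vc)
            g = numeric_gradient(lambda th: th[0] / (th[0] + th[1]), [a, e])
            se_num = np.sqrt(g @ cov @ g)
            assert se == pytest.approx(se_num, abs=1e-8)

    def test_correlation_ses_match_numeric_propagation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g11, g22, r11, r22 = rng.uniform(0.2, 2.0, size=4)
            g12 = rng.uniform(-0.9, 0.9) * np.sqrt(g11 * g22)
            r12 = rng.uniform(-0.9, 0.9) * np.sqrt(r11 * r22)
            M = rng.standard_normal((6, 6)) * 0.03
            cov = M @ M.T + 1e-5 * np.eye(6)
            bc = BivariateComponents(
                G=np.array([[g11, g12], [g12, g22]]),
                R=np.array([[r11, r12], [r12, r22]]),
                sampling_cov=cov, loglik=0.0, converged=True,
                boundary=False, residual_cov_estimated=True, trace=[])
            (rg, rg_se), (rp, rp_se) = correlations(bc)

            def rg_fn(th):
                return th[1] / np.sqrt(th[0] * th[2])

            def rp_fn(th):
                return (th[1] + th[4]) / np.sqrt(
                    (th[0] + th[3]) * (th[2] + th[5]))

            th0 = bc.theta
            for fn, se in ((rg_fn, rg_se), (rp_fn, rp_se)):
                g = numeric_gradient(fn, th0)
                assert se == pytest.approx(np.sqrt(g @ cov @ g), abs=1e-8)

    def test_zero_genetic_covariance_gives_zero_rg(self):
        bc = BivariateComponents(
            G=np.diag([0.5, 0.5]), R=np.diag([0.5, 0.5]),
            sampling_cov=np.eye(6) * 1e-4, loglik=0.0, converged=True,
            boundary=False, residual_cov_estimated=True, trace=[])
        (rg, _), (rp, _) = correlations(bc)
        assert rg == 0.0 and rp == 0.0

    def test_rp_equals_rg_when_G_equals_R(self):
        G = np.array([[1.0, 0.6], [0.6, 1.0]])
        bc = BivariateComponents(
            G=G, R=G.copy(), sampling_cov=np.eye(6) * 1e-4, loglik=0.0,
            converged=True, boundary=False, residual_cov_estimated=True,
            trace=[])
        (rg, _), (rp, _) = correlations(bc)
        assert rg == pytest.approx(rp)

    def test_select_heritability_rules(self):
        uni = GeneticParameters(h2=0.5, h2_se=0.14, source="univariate")
        biv = GeneticParameters(h2=0.52, h2_se=0.12, source="bivariate(a__b)")
        assert select_heritability(uni, [biv]) is biv
        tie = GeneticParameters(h2=0.55, h2_se=0.14, source="bivariate(a__b)")
        assert select_heritability(uni, [tie]) is uni
        assert select_heritability(uni, []) is uni
        with pytest.raises(ValueError):
            select_heritability(
                GeneticParameters(h2=0.5, h2_se=float("nan")), [])


class TestBLUP:
    def test_ebv_accuracy_at_design_scale(self, analysis_population):
        aped, rm, table = analysis_population
        ds = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        vc, fit = reml_univariate(ds, rm, REMLOptions())
        truth = table.set_index("animal")["bv_trait"]
        phen = table.loc[table["trait"].notna(), "animal"]
        r_ebv = np.corrcoef(fit.ebv.loc[phen, "trait"], truth.loc[phen])[0, 1]
        assert r_ebv > 0.6

    def test_unphenotyped_founders_get_nonzero_ebvs(self, analysis_population):
        aped, rm, table = analysis_population
        ds = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        _, fit = reml_univariate(ds, rm, REMLOptions())
        founders = [str(a) for a, f in zip(aped.ids, aped.is_founder) if f]
        ebv_f0 = fit.ebv.loc[founders].iloc[:, 0]
        assert np.any(np.abs(ebv_f0) > 0.05)
        # and PEV of unphenotyped parents exceeds that of phenotyped animals
        phen = [str(a) for a in
                np.array(aped.ids)[np.unique(ds.traits[0].animal_idx)]]
        assert fit.pev.loc[founders].iloc[:, 0].mean() > \
            fit.pev.loc[phen].iloc[:, 0].mean()

    def test_variance_floor_shrinks_all_ebvs_to_zero(self):
        rng = np.random.default_rng(9)
        y, X, K = _toy_system(rng, n=50, h2=0.0)
        vc, fit = _fit_direct(y, X, K, REMLOptions())
        assert vc.boundary
        assert np.max(np.abs(fit.ebv.iloc[:, 0])) < 1e-3

    def test_histogram_export(self, analysis_population):
        aped, rm, table = analysis_population
        ds = build_design(table, TraitSpec("trait", age_column="age_2m"), aped)
        _, fit = reml_univariate(ds, rm, REMLOptions())
        ebv, hists = predict_ebv(fit, bins=20)
        edges, counts = hists["trait"]
        assert counts.sum() == len(ebv)
        assert len(edges) == 21
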