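"""The synthetic F2 resource-population generator."""

import numpy as np
import pandas as pd
import pytest

from f2quant.pedigree import additive_relationship_matrix
from f2quant.simulate import (DesignConfig, DesignError, GeneticArchitecture,
                              SimTrait, simulate_breeding_values,
                              simulate_design, simulate_phenotypes,
                              single_trait_architecture,
                              two_trait_architecture, write_phenotypes)


class TestDesign:
    def test_design_counts_match_reference_intercross(self, design_population):
        ped, cov = design_population
        assert int((ped.generation == "F0").sum()) == 28
        assert int((ped.generation == "F1").sum()) == 127
        f2 = cov[cov.generation == "F2"]
        assert len(f2) == 474
        assert int(f2.retained.sum()) == 454

    def test_litter_sizes_within_printed_range(self, design_population):
        _, cov = design_population
        sizes = cov[cov.generation == "F2"].groupby("litter").size()
        assert sizes.min() >= 2 and sizes.max() <= 12

    def test_f1_parent_selection_counts(self, design_population):
        ped, _ = design_population
        f1_idx = np.nonzero(ped.generation == "F1")[0]
        used = set(ped.sire[ped.generation == "F2"]) | \
            set(ped.dam[ped.generation == "F2"])
        f1_parents = [i for i in f1_idx if i in used]
        assert len(f1_parents) == 81

    def test_boars_used_once_or_twice_never_on_litter_mates(self, design_population):
        ped, cov = design_population
        f2 = np.nonzero(ped.generation == "F2")[0]
        litters = {}
        for i in f2:
            litters.setdefault((ped.sire[i], ped.dam[i]), 0)
        sire_use = {}
        for s, d in litters:
            sire_use[s] = sire_use.get(s, 0) + 1
            # non-litter-mate: parents of sire != parents of dam
            assert (ped.sire[s], ped.dam[s]) != (ped.sire[d], ped.dam[d])
        assert set(sire_use.values()) <= {1, 2}

    def test_seed_reproducibility(self):
        ped1, cov1 = simulate_design(DesignConfig(), seed=9)
        ped2, cov2 = simulate_design(DesignConfig(), seed=9)
        assert list(ped1.ids) == list(ped2.ids)
        pd.testing.assert_frame_equal(cov1, cov2)
        ped3, _ = simulate_design(DesignConfig(), seed=10)
        assert not np.array_equal(
            np.array(ped1.sire), np.array(ped3.sire))

    def test_retained_equals_born_minus_losses(self):
        cfg = DesignConfig(n_f2_born=400, n_dead_early=10, n_removed=20)
        _, cov = simulate_design(cfg, seed=1)
        f2 = cov[cov.generation == "F2"]
        assert int(f2.retained.sum()) == 370

    def test_infeasible_litter_partition_raises(self):
        with pytest.raises(DesignError):
            # 53 litters cannot reach 1000 piglets at <= 12 per litter
            simulate_design(DesignConfig(n_f2_born=1000), seed=0)

    def test_ages_increase_across_timepoints(self, design_population):
        _, cov = design_population
        f2 = cov[cov.generation == "F2"]
        cols = ["age_birth", "age_2w", "age_5w", "age_2m", "age_125d", "age_7m"]
        mat = f2[cols].to_numpy(dtype=float)
        assert np.all(np.diff(mat, axis=1) > 0)


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_bvs(self, design_population):
        ped, _ = design_population
        arch = GeneticArchitecture(
            traits=[SimTrait(name="t")], G=np.array([[0.0]]),
            R=np.array([[1.0]]))
        bv = simulate_breeding_values(ped, arch, seed=0)
        assert np.all(bv == 0.0)

    def test_founder_variance_matches_target(self):
        from f2quant.pedigree import pedigree_from_records
        ped = pedigree_from_records(
            [(f"A{i}", "0", "0") for i in range(2000)])
        arch = single_trait_architecture(h2=0.5, phenotypic_var=2.0)  # sa2=1
        bv = simulate_breeding_values(ped, arch, seed=1)
        assert 0.9 < np.var(bv[:, 0], ddof=1) < 1.1

    def test_bv_covariance_matches_relationship_matrix(self):
        # gene-drop replicates: empirical cov of BVs approaches A * sigma2_a
        from f2quant.pedigree import pedigree_from_records
        ped = pedigree_from_records(
            [("S", "0", "0"), ("D", "0", "0"), ("X", "S", "D"),
             ("Y", "S", "D"), ("Z", "X", "Y")])
        A = additive_relationship_matrix(ped).A
        arch = single_trait_architecture(h2=1.0, phenotypic_var=1.0)
        reps = np.stack([
            simulate_breeding_values(ped, arch, seed=s)[:, 0]
            for s in range(4000)])
        emp = np.cov(reps.T)
        assert np.max(np.abs(emp - A)) < 0.12  # Monte-Carlo tolerance

    def test_non_psd_G_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            GeneticArchitecture(
                traits=[SimTrait(name="a"), SimTrait(name="b")],
                G=np.array([[1.0, 2.0], [2.0, 1.0]]), R=np.eye(2))


class TestPhenotypes:
    def test_pure_genetic_signal(self, design_population):
        ped, cov = design_population
        arch = GeneticArchitecture(
            traits=[SimTrait(name="t", mean=5.0)], G=np.array([[1.0]]),
            R=np.array([[0.0]]))
        table = simulate_phenotypes(ped, cov, arch, seed=3)
        got = table.dropna(subset=["t"])
        assert np.allclose(got["t"], 5.0 + got["bv_t"])

    def test_configured_missingness_exact(self, design_population):
        ped, cov = design_population
        arch = single_trait_architecture(h2=0.5, missing_n=146)
        table = simulate_phenotypes(ped, cov, arch, seed=4)
        assert int(table["trait"].notna().sum()) == 146

    def test_phenotype_regression_on_bv_has_unit_slope(self, design_population):
        # across replicates the BV enters the phenotype with coefficient 1
        ped, cov = design_population
        arch = single_trait_architecture(h2=0.5)
        slopes = []
        for s in range(25):
            tab = simulate_phenotypes(ped, cov, arch, seed=s).dropna(
                subset=["trait"])
            b = np.polyfit(tab["bv_trait"], tab["trait"], 1)[0]
            slopes.append(b)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)

    def test_sib_covariance_reflects_target_heritability(self, design_population):
        # full-sib phenotypic covariance ~ 0.5 sigma2_a (plus inbreeding terms)
        ped, cov = design_population
        arch = single_trait_architecture(
            h2=0.5, sex_effect=0.0, sob_effects=(0, 0, 0), age_slope=0.0)
        covs = []
        for s in range(40):
            tab = simulate_phenotypes(ped, cov, arch, seed=100 + s)
            tab = tab.dropna(subset=["trait"])
            y = tab["trait"].to_numpy()
            num = den = 0.0
            for _, grp in tab.groupby("litter")["trait"]:
                d = grp.to_numpy() - y.mean()
                num += d.sum() ** 2 - (d**2).sum()   # sum over ordered pairs
                den += len(d) * (len(d) - 1)
            covs.append(num / den)
        h2_sib = 2 * np.mean(covs)  # phenotypic variance is 1
        assert h2_sib == pytest.approx(0.5, abs=0.12)

    def test_length_covariate_requires_prior_trait(self, design_population):
        ped, cov = design_population
        with pytest.raises(ValueError, match="not simulated"):
            GeneticArchitecture(
                traits=[SimTrait(name="fat", length_slope=0.1,
                                 length_source="length")],
                G=np.eye(1), R=np.eye(1))

    def test_length_covariate_enters_dependent_trait(self, design_population):
        ped, cov = design_population
        arch = GeneticArchitecture(
            traits=[SimTrait(name="length", mean=50.0),
                    SimTrait(name="fat", length_slope=2.0,
                             length_source="length")],
            G=0.5 * np.eye(2), R=0.5 * np.eye(2))
        tab = simulate_phenotypes(ped, cov, arch, seed=6).dropna(subset=["fat"])
        r = np.corrcoef(tab["length"], tab["fat"])[0, 1]
        assert r > 0.8

    def test_line_divergence_shifts_f2_mean(self, design_population):
        ped, cov = design_population
        base = SimTrait(name="t", line_offsets={"M": 10.0})
        arch = GeneticArchitecture(traits=[base], G=np.eye(1) * 1e-12,
                                   R=np.eye(1) * 1e-12)
        tab = simulate_phenotypes(ped, cov, arch, seed=7).dropna(subset=["t"])
        # F2 carry half the minipig genome in expectation
        assert np.allclose(tab["t"], 5.0, atol=1e-3)

    def test_writer_omits_true_breeding_values(self, tmp_path, design_population):
        ped, cov = design_population
        arch = single_trait_architecture(h2=0.5)
        tab = simulate_phenotypes(ped, cov, arch, seed=8)
        path = tmp_path / "pheno.csv"
        write_phenotypes(tab, path)
        again = pd.read_csv(path)
        assert "bv_trait" not in again.columns
        assert "trait" in again.columns


class TestArchitectures:
    def test_two_trait_targets(self):
        arch = two_trait_architecture(0.43, 0.78, 0.90, re=0.5)
        G, R = arch.G, arch.R
        assert G[0, 0] + R[0, 0] == pytest.approx(1.0)
        assert G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]) == pytest.approx(0.90)
        assert R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]) == pytest.approx(0.5)
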