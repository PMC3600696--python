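import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from f2quant.pedigree import (additive_relationship_matrix, pedigree_from_records,
                              prune_to_phenotyped)
from f2quant.simulate import (DesignConfig, simulate_design,
                              simulate_phenotypes, single_trait_architecture)


@pytest.fixture(scope="session")
def design_population():
    """One simulated resource population (pedigree, covariates), seed-fixed."""
    return simulate_design(DesignConfig(), seed=42)


@pytest.fixture(scope="session")
def analysis_population(design_population):
    """Phenotyped population with h2=0.5 trait, pruned analysis pedigree + A."""
    ped, cov = design_population
    arch = single_trait_architecture(h2=0.5)
    table = simulate_phenotypes(ped, cov, arch, seed=42)
    retained = table.loc[table["retained"].astype(bool), "animal"]
    aped = prune_to_phenotyped(ped, retained)
    rm = additive_relationship_matrix(aped)
    return aped, rm, table


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return pedigree_from_records([
        ("S", "0", "0", "M"), ("D", "0", "0", "F"), ("X", "S", "D", "M")])


@pytest.fixture
def fullsib_mating_pedigree():
    """Offspring of full sibs whose parents are unrelated founders."""
    return pedigree_from_records([
        ("GS", "0", "0"), ("GD", "0", "0"),
        ("S", "GS", "GD"), ("D", "GS", "GD"), ("X", "S", "D")])
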