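"""Replicate simulation-and-refit experiments at the design scale.

Parameter-recovery loops used by the validation suite and the reproduction
script: simulate a full resource population with a known architecture,
re-estimate by REML on the pruned analysis pedigree, and summarise across
replicates.
"""

from __future__ import annotations

import numpy as np

from .mixed_model import (REMLOptions, build_design, correlations,
                          heritability, reml_bivariate, reml_univariate)
from .pedigree import additive_relationship_matrix, prune_to_phenotyped
from .simulate import (DesignConfig, single_trait_architecture,
                       simulate_design, simulate_phenotypes,
                       two_trait_architecture)
from .traits import TraitSpec

_FAST = REMLOptions(compute_ebv=False, compute_pev=False)


def _analysis_inputs(cfg: DesignConfig, arch, seed: int):
    ped, cov = simulate_design(cfg, seed=seed)
    table = simulate_phenotypes(ped, cov, arch, seed=seed)
    retained = table.loc[table["retained"].astype(bool), "animal"]
    aped = prune_to_phenotyped(ped, retained)
    rm = additive_relationship_matrix(aped)
    return aped, rm, table


def recovery_univariate(
    true_h2: float,
    n_replicates: int,
    seed: int = 0,
    missing_n: int | None = None,
    cfg: DesignConfig | None = None,
) -> dict:
    """Replicate univariate h2 recovery on the F2 design.

    Each replicate simulates a fresh population (pedigree and data) with the
    target heritability, fits the univariate animal model with sex, season
    and age fixed effects, and records the h2 estimate.
    """
    cfg = cfg or DesignConfig()
    arch = single_trait_architecture(h2=true_h2, missing_n=missing_n)
    spec = TraitSpec(name="trait", age_column="age_2m")
    estimates, ses, converged = [], [], 0
    for rep in range(n_replicates):
        rep_seed = (seed * 100_003 + rep) % 2**31
        aped, rm, table = _analysis_inputs(cfg, arch, rep_seed)
        ds = build_design(table, spec, aped)
        vc, _fit = reml_univariate(ds, rm, _FAST)
        h2, se = heritability(vc)
        estimates.append(h2)
        ses.append(se)
        converged += vc.converged
    estimates = np.array(estimates)
    return {
        "true_h2": true_h2,
        "estimates": estimates,
        "mean": float(estimates.mean()),
        "sd": float(estimates.std(ddof=1)) if n_replicates > 1 else 0.0,
        "mean_se": float(np.mean(ses)),
        "n_converged": int(converged),
        "n_records": int(len(ds.traits[0].y)),
    }


def recovery_bivariate(
    h2_1: float,
    h2_2: float,
    true_rg: float,
    re: float = 0.5,
    n_replicates: int = 30,
    seed: int = 0,
) -> dict:
    """Replicate bivariate rg recovery on the F2 design."""
    cfg = DesignConfig()
    arch = two_trait_architecture(h2_1, h2_2, true_rg, re=re)
    specs = [TraitSpec(name="trait1", age_column="age_2m"),
             TraitSpec(name="trait2", age_column="age_2m")]
    rgs, rps, converged = [], [], 0
    for rep in range(n_replicates):
        rep_seed = (seed * 100_003 + rep) % 2**31
        aped, rm, table = _analysis_inputs(cfg, arch, rep_seed)
        ds = build_design(table, specs, aped)
        bc, _fit = reml_bivariate(ds, rm, _FAST)
        (rg, _), (rp, _) = correlations(bc)
        if rg is not None:
            rgs.append(rg)
        rps.append(rp)
        converged += bc.converged
    rgs = np.array(rgs)
    return {
        "true_rg": true_rg,
        "estimates": rgs,
        "mean": float(rgs.mean()),
        "sd": float(rgs.std(ddof=1)) if len(rgs) > 1 else 0.0,
        "mean_rp": float(np.mean(rps)),
        "n_converged": int(converged),
    }
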