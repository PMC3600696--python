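"""Configuration-driven end-to-end runs with reproducible report bundles.

One run mirrors the full analysis of the resource population: obtain data
(simulate or load), descriptive statistics, fixed-effect screening,
univariate REML per trait, bivariate REML per pair, lowest-SE heritability
selection, a correlation matrix report (genetic above / phenotypic below the
diagonal), EBV tables with histogram data, power calculations, and a JSON
manifest tying every number to its fit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .mixed_model import (GeneticParameters, REMLOptions, build_design,
                          correlations, heritabilities_bivariate, heritability,
                          predict_ebv, reml_bivariate, reml_univariate,
                          screen_fixed_effects, select_heritability)
from .pedigree import (additive_relationship_matrix, prune_to_phenotyped,
                       read_pedigree, write_pedigree)
from .power import PowerQuery, f2_qtl_power
from .simulate import simulate_design, simulate_phenotypes, write_phenotypes
from .traits import descriptives_table

log = logging.getLogger("f2quant")


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        self.stage = stage
        super().__init__(f"[{stage}] {original}")


def _fmt(value, se) -> str:
    if value is None or not np.isfinite(value):
        return "n.e."
    flag = "*" if se is not None and np.isfinite(se) and abs(value) > 2 * se else ""
    return f"{value:.2f} ({se:.2f}){flag}" if se is not None else f"{value:.2f}"


def _component_json(components) -> dict:
    out = dataclasses.asdict(components)
    for key, val in out.items():
        if isinstance(val, np.ndarray):
            out[key] = val.tolist()
    out["trace"] = [(int(i), float(ll), np.asarray(th).tolist())
                    for i, ll, th in components.trace]
    return out


def run_pipeline(cfg: RunConfig, output_dir: str | None = None) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    All outputs are plain TSV/CSV/JSON under ``output_dir``; a fixed seed
    yields byte-identical bundles.  Non-converged fits are reported as
    missing with a reason, never silently dropped.
    """
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                "version": __version__, "mode": cfg.mode,
                "outputs": [], "nonconverged": [], "complete": False}

    def emit(name):
        manifest["outputs"].append(name)
        return out / name

    stage = "data"
    try:
        if cfg.mode == "simulate":
            ped, cov = simulate_design(cfg.design, seed=cfg.seed)
            table = simulate_phenotypes(ped, cov, cfg.architecture, seed=cfg.seed)
            write_pedigree(ped, emit("pedigree.csv"))
            write_phenotypes(table, emit("phenotypes.csv"))
        else:
            ped = read_pedigree(cfg.pedigree_path)
            table = pd.read_csv(cfg.phenotype_path)

        trait_names = [s.name for s in cfg.trait_specs]
        has_record = table[trait_names].notna().any(axis=1)
        aped = prune_to_phenotyped(ped, table.loc[has_record, "animal"])
        rm = additive_relationship_matrix(aped)
        opts = REMLOptions(**cfg.reml) if cfg.reml else REMLOptions()

        stage = "descriptives"
        desc = descriptives_table(table, cfg.trait_specs)
        desc.to_csv(emit("descriptives.tsv"), sep="\t", index=False,
                    float_format="%.2f")

        stage = "screening"
        rows = []
        for spec in cfg.trait_specs:
            cands = [f for f in spec.fixed_factors]
            covs = [spec.age_column] if spec.use_age else []
            try:
                for res in screen_fixed_effects(table, spec, cands,
                                                covariates=covs):
                    rows.append({"trait": spec.name, "effect": res.effect,
                                 "F": res.f_statistic, "df": res.df,
                                 "p": res.p_value,
                                 "significant": res.significant})
            except ValueError as exc:
                rows.append({"trait": spec.name, "effect": "-", "F": np.nan,
                             "df": 0, "p": np.nan,
                             "significant": f"error: {exc}"})
        pd.DataFrame(rows).to_csv(emit("screening.tsv"), sep="\t", index=False)

        stage = "univariate"
        uni_params: dict[str, GeneticParameters] = {}
        for spec in cfg.trait_specs:
            ds = build_design(table, spec, aped)
            vc, fit = reml_univariate(ds, rm, opts)
            with open(out / "fits" / f"{spec.name}.json", "w") as fh:
                json.dump(_component_json(vc), fh, indent=1)
            manifest["outputs"].append(f"fits/{spec.name}.json")
            if not vc.converged:
                manifest["nonconverged"].append(
                    {"fit": spec.name, "reason": "univariate REML did not "
                     "reach the convergence tolerance"})
            h2, se = heritability(vc)
            uni_params[spec.name] = GeneticParameters(
                h2=h2, h2_se=se, source="univariate")
            if fit.ebv is not None:
                ebv, hists = predict_ebv(fit)
                ebv.round(6).to_csv(emit(f"ebv_{spec.name}.tsv"), sep="\t")
                edges, counts = hists[spec.name]
                pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                              "count": counts}).to_csv(
                    emit(f"ebv_hist_{spec.name}.tsv"), sep="\t", index=False)

        stage = "bivariate"
        biv_h2: dict[str, list[GeneticParameters]] = {t: [] for t in trait_names}
        rg_mat = pd.DataFrame("n.e.", index=trait_names, columns=trait_names)
        spec_of = {s.name: s for s in cfg.trait_specs}
        for t1, t2 in cfg.resolved_pairs():
            pair_name = f"{t1}__{t2}"
            ds = build_design(table, [spec_of[t1], spec_of[t2]], aped)
            bc, _fit = reml_bivariate(ds, rm, opts)
            with open(out / "fits" / f"{pair_name}.json", "w") as fh:
                json.dump(_component_json(bc), fh, indent=1)
            manifest["outputs"].append(f"fits/{pair_name}.json")
            if not bc.converged:
                manifest["nonconverged"].append(
                    {"fit": pair_name, "reason": "bivariate REML did not "
                     "reach the convergence tolerance"})
                continue
            (rg, rg_se), (rp, rp_se) = correlations(bc)
            rg_mat.loc[t1, t2] = _fmt(rg, rg_se)     # genetic above diagonal
            rg_mat.loc[t2, t1] = _fmt(rp, rp_se)     # phenotypic below
            for name, (h2, se) in zip((t1, t2), heritabilities_bivariate(bc)):
                biv_h2[name].append(GeneticParameters(
                    h2=h2, h2_se=se, source=f"bivariate({pair_name})"))

        stage = "heritability-report"
        rows = []
        for name in trait_names:
            uni = uni_params[name]
            sel = select_heritability(uni, biv_h2[name])
            rows.append({"trait": name,
                         "h2_univariate": round(uni.h2, 2),
                         "se_univariate": round(uni.h2_se, 2),
                         "h2_selected": round(sel.h2, 2),
                         "se_selected": round(sel.h2_se, 2),
                         "source": sel.source})
        pd.DataFrame(rows).to_csv(emit("heritability.tsv"), sep="\t", index=False)
        for t in trait_names:
            rg_mat.loc[t, t] = "-"
        with open(emit("correlations.tsv"), "w") as fh:
            fh.write("# genetic correlations above the diagonal, phenotypic "
                     "below; 'estimate (SE)', * = |estimate| > 2 SE\n")
            rg_mat.to_csv(fh, sep="\t")

        stage = "power"
        rows = []
        for node in cfg.power_queries:
            q = PowerQuery(**node)
            res = f2_qtl_power(q)
            rows.append({**dataclasses.asdict(q), "power": res.power,
                         "noncentrality": res.noncentrality,
                         "threshold": res.threshold})
        if rows:
            pd.DataFrame(rows).to_csv(emit("power.tsv"), sep="\t", index=False)

        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    return manifest
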