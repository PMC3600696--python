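"""Design-matrix construction and fixed-effect screening for animal models."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..pedigree import Pedigree
from ..traits import TraitSpec, transform


class DesignSpaceError(ValueError):
    pass


@dataclasses.dataclass
class TraitDesign:
    """One trait's aligned response / fixed-design / animal mapping."""

    trait: str
    y: np.ndarray                # transformed responses
    X: np.ndarray                # fixed-effects incidence, full column rank
    x_names: list[str]
    animal_idx: np.ndarray       # pedigree positions, one per record
    n_dropped: int


@dataclasses.dataclass
class DesignSystem:
    """Aligned system for one trait or a stacked pair of traits."""

    traits: list[TraitDesign]
    ped: Pedigree

    @property
    def is_pair(self) -> bool:
        return len(self.traits) == 2

    @property
    def overlap(self) -> np.ndarray:
        """Pedigree indices of animals recorded for every trait."""
        sets = [set(t.animal_idx.tolist()) for t in self.traits]
        return np.array(sorted(set.intersection(*sets)), dtype=int)


def _factor_columns(values: np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    """Reference (corner-point) coding: first sorted level is the reference."""
    levels = sorted(pd.unique(values[pd.notna(values)]), key=str)
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).astype(float))
        names.append(f"{name}[{lev}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def _single_trait_design(
    table: pd.DataFrame, spec: TraitSpec, ped: Pedigree
) -> TraitDesign:
    if spec.name not in table.columns:
        raise DesignSpaceError(f"trait {spec.name!r} not in phenotype table")
    work = table.copy()
    needed = [spec.name]
    if spec.use_age:
        needed.append(spec.age_column)
    if spec.use_length:
        needed.append(spec.length_column)
    for col in needed:
        if col not in work.columns:
            raise DesignSpaceError(f"column {col!r} not in phenotype table")
    keep = np.ones(len(work), dtype=bool)
    for col in needed:
        keep &= pd.notna(work[col]).to_numpy()
    for fac in spec.fixed_factors:
        keep &= pd.notna(work[fac]).to_numpy()
    n_dropped = int(len(work) - keep.sum())
    work = work.loc[keep]
    if len(work) == 0:
        raise DesignSpaceError(f"no usable records for trait {spec.name!r}")

    y = transform(work[spec.name].to_numpy(dtype=float), spec.transformation)
    blocks = [np.ones((len(work), 1))]
    names = ["intercept"]
    for fac in spec.fixed_factors:
        cols, cn = _factor_columns(work[fac].to_numpy(), fac)
        blocks.append(cols)
        names.extend(cn)
    for use, col in ((spec.use_age, spec.age_column),
                     (spec.use_length, spec.length_column)):
        if use:
            v = work[col].to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])   # centred covariate
            names.append(col)
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignSpaceError(
            f"rank-deficient fixed-effects design for {spec.name!r}; "
            f"columns: {names}")
    animal_idx = ped.index_of(work["animal"])
    return TraitDesign(trait=spec.name, y=y, X=X, x_names=names,
                       animal_idx=animal_idx, n_dropped=n_dropped)


def build_design(
    table: pd.DataFrame,
    spec: TraitSpec | Sequence[TraitSpec],
    ped: Pedigree,
) -> DesignSystem:
    """Aligned response / design / animal mapping for one trait or a pair.

    Records missing the response or any required covariate are dropped.
    Factors use reference coding on the first sorted level and numeric
    covariates are centred; pairs are kept as separate per-trait blocks
    (the stacked system permits different record sets per trait).
    """
    specs = [spec] if isinstance(spec, TraitSpec) else list(spec)
    if len(specs) not in (1, 2):
        raise DesignSpaceError("build_design takes one trait or a pair")
    designs = [_single_trait_design(table, s, ped) for s in specs]
    return DesignSystem(traits=designs, ped=ped)


@dataclasses.dataclass
class ScreeningResult:
    effect: str
    df: int
    f_statistic: float
    p_value: float
    significant: bool


def screen_fixed_effects(
    table: pd.DataFrame,
    spec: TraitSpec,
    candidates: Sequence[str],
    alpha: float = 0.05,
    covariates: Sequence[str] = (),
) -> list[ScreeningResult]:
    """Preliminary least-squares screen of candidate fixed effects.

    Fits the trait on all candidates jointly by OLS and evaluates each with a
    drop-one partial F test; effects with p < ``alpha`` are flagged for the
    animal model.  ``candidates`` are categorical factors; ``covariates``
    numeric columns entered linearly (also tested drop-one).
    """
    cols = [spec.name, *candidates, *covariates]
    for c in cols:
        if c not in table.columns:
            raise DesignSpaceError(f"column {c!r} not in phenotype table")
    work = table.dropna(subset=cols)
    y = transform(work[spec.name].to_numpy(dtype=float), spec.transformation)
    n = len(work)

    blocks: dict[str, np.ndarray] = {}
    for fac in candidates:
        vals = work[fac].to_numpy()
        if len(pd.unique(vals)) < 2:
            raise DesignSpaceError(f"factor {fac!r} has a single level")
        cols_f, _ = _factor_columns(vals, fac)
        blocks[fac] = cols_f
    for cov in covariates:
        v = work[cov].to_numpy(dtype=float)
        blocks[cov] = (v - v.mean())[:, None]

    def rss_of(effects: Sequence[str]) -> tuple[float, int]:
        X = np.column_stack(
            [np.ones((n, 1))] + [blocks[e] for e in effects]) if effects else np.ones((n, 1))
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DesignSpaceError(
                f"rank-deficient screening design; aliased among {list(effects)}")
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid), X.shape[1]

    all_effects = list(candidates) + list(covariates)
    rss_full, p_full = rss_of(all_effects)
    results = []
    for eff in all_effects:
        rss_red, p_red = rss_of([e for e in all_effects if e != eff])
        q = p_full - p_red
        dfe = n - p_full
        F = ((rss_red - rss_full) / q) / (rss_full / dfe)
        pval = float(stats.f.sf(F, q, dfe))
        results.append(ScreeningResult(
            effect=eff, df=q, f_statistic=float(F), p_value=pval,
            significant=pval < alpha))
    return results
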