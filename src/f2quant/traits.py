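"""Derived obesity traits, exclusion filters, transformations, descriptives.

Covers the derived measurements of the phenotyping protocol: predicted lean
meat percentage from Fat-o-Meat'er probes, the reflectance exclusion rule for
very fat carcasses, body-mass and body-adiposity indices, growth rates, the
normalising transformations, and Table-style descriptive statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: reflectance above this value marks a Fat-o-Meat'er probe as unreliable
REFLECTANCE_CUTOFF = 65.0

#: coefficients of the lean-meat prediction equation
MEAT_INTERCEPT = 66.7393
MEAT_BF1_COEF = -0.2655
MEAT_BF2_COEF = -0.5432
MEAT_MUSCLE_COEF = 0.0838


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """How one trait enters the animal model.

    ``transformation`` is applied to the raw values before analysis; the
    fixed part of the model is built from ``fixed_factors`` (categorical)
    plus the ``age_column`` covariate and, when ``use_length``, the
    ``length_column`` covariate (the body-length adjustment used for mass
    traits).
    """

    name: str
    transformation: str = "none"          # none | log10 | sqrt
    fixed_factors: tuple[str, ...] = ("sex", "sob")
    use_age: bool = True
    use_length: bool = False
    age_column: str = "age"
    length_column: str = "length"
    unit: str = ""

    def __post_init__(self):
        if self.transformation not in ("none", "log10", "sqrt"):
            raise ValueError(f"unknown transformation {self.transformation!r}")


@dataclasses.dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    cv_percent: float


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def meat_percentage(x1, x2, x3):
    """Lean-meat percentage predicted from carcass probe measurements.

    ``x1``/``x2`` are backfat depths (mm) at the two probe positions and
    ``x3`` the muscle depth (mm) at position 2; all must be non-negative.
    """
    x1, x2, x3 = _asarray(x1), _asarray(x2), _asarray(x3)
    for name, v in (("x1", x1), ("x2", x2), ("x3", x3)):
        with np.errstate(invalid="ignore"):
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"negative {name} measurement")
    out = (MEAT_INTERCEPT + MEAT_BF1_COEF * x1 + MEAT_BF2_COEF * x2
           + MEAT_MUSCLE_COEF * x3)
    return float(out) if out.ndim == 0 else out


def reflectance_filter(values, reflectance):
    """Mask measurements whose probe reflectance exceeds the cutoff.

    Entries with reflectance strictly greater than 65 become NaN; the cutoff
    itself (65) is retained.  Fat depth correlates with reflectance, so very
    obese carcasses give unreliable optical readings.
    """
    values = _asarray(values).copy()
    reflectance = _asarray(reflectance)
    if values.shape != reflectance.shape:
        raise ValueError("values and reflectance must have equal length")
    values[reflectance > REFLECTANCE_CUTOFF] = np.nan
    return values


def bmi(weight, length):
    """Body-mass index, weight / length**2 (weight kg, length metres)."""
    weight, length = _asarray(weight), _asarray(length)
    if np.any(length[np.isfinite(length)] <= 0):
        raise ValueError("length must be positive")
    out = weight / length**2
    return float(out) if out.ndim == 0 else out


def bai(abdominal_circumference, length):
    """Body-adiposity index, abdominal circumference / length**1.5 (both cm)."""
    circ, length = _asarray(abdominal_circumference), _asarray(length)
    if np.any(length[np.isfinite(length)] <= 0):
        raise ValueError("length must be positive")
    out = circ / length**1.5
    return float(out) if out.ndim == 0 else out


def daily_gains(
    ages: Sequence[float],
    weights: Sequence[float],
    weaning_age: float,
) -> tuple[float, float, float]:
    """(ADG, DGI, DGII) growth rates in kg/day from a weight series.

    ADG spans the whole recorded period (first to last weight); DGI the
    pre-weaning and DGII the post-weaning segment, each anchored at the
    recorded weights nearest to (and bracketing) the weaning age.  An
    interval that is not covered by the records yields NaN.
    """
    ages = _asarray(ages)
    weights = _asarray(weights)
    if ages.shape != weights.shape:
        raise ValueError("ages and weights must align")
    ok = np.isfinite(ages) & np.isfinite(weights)
    ages, weights = ages[ok], weights[ok]
    if len(ages) and np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    nan = float("nan")
    if len(ages) < 2:
        return nan, nan, nan
    adg = (weights[-1] - weights[0]) / (ages[-1] - ages[0])

    before = np.nonzero(ages <= weaning_age)[0]
    after = np.nonzero(ages >= weaning_age)[0]
    # boundary record: nearest recorded age to weaning (ties to the earlier one)
    if len(before) and len(after):
        lo, hi = before[-1], after[0]
        split = lo if abs(ages[lo] - weaning_age) <= abs(ages[hi] - weaning_age) else hi
    else:
        split = None
    dgi = dgii = nan
    if split is not None and split > 0:
        dgi = (weights[split] - weights[0]) / (ages[split] - ages[0])
    if split is not None and split < len(ages) - 1:
        dgii = (weights[-1] - weights[split]) / (ages[-1] - ages[split])
    return float(adg), float(dgi), float(dgii)


def transform(values, kind: str):
    """Elementwise log10 or sqrt; NaN propagates; domain violations raise."""
    values = _asarray(values)
    finite = np.isfinite(values)
    if kind == "log10":
        bad = np.nonzero(finite & (values <= 0))[0]
        if bad.size:
            raise ValueError(f"log10 domain violation at indices {bad.tolist()[:10]}")
        out = np.where(finite, np.log10(np.where(finite & (values > 0), values, 1.0)), np.nan)
    elif kind == "sqrt":
        bad = np.nonzero(finite & (values < 0))[0]
        if bad.size:
            raise ValueError(f"sqrt domain violation at indices {bad.tolist()[:10]}")
        out = np.where(finite, np.sqrt(np.where(finite & (values >= 0), values, 0.0)), np.nan)
    elif kind == "none":
        out = values.copy()
    else:
        raise ValueError(f"unknown transformation {kind!r}")
    return out


def inverse_transform(values, kind: str):
    values = _asarray(values)
    if kind == "log10":
        return 10.0 ** values
    if kind == "sqrt":
        return values**2
    if kind == "none":
        return values.copy()
    raise ValueError(f"unknown transformation {kind!r}")


def apply_trait_spec(values, spec: TraitSpec):
    return transform(values, spec.transformation)


def descriptive_stats(values) -> DescriptiveStats:
    """n, mean, sample SD (n-1), min, max, CV% = 100 sd/mean over non-missing."""
    values = _asarray(values)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least two non-missing values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return DescriptiveStats(
        n=len(values), mean=mean, sd=sd,
        min=float(np.min(values)), max=float(np.max(values)), cv_percent=cv)


def outlier_report(values, n_sd: float = 4.0) -> np.ndarray:
    """Indices of values further than ``n_sd`` sample SDs from the mean.

    Flagged for manual review only; nothing is removed automatically.
    """
    values = _asarray(values)
    ok = np.isfinite(values)
    mu = values[ok].mean()
    sd = values[ok].std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.nonzero(ok & (np.abs(values - mu) > n_sd * sd))[0]


def descriptives_table(table: pd.DataFrame, specs: Sequence[TraitSpec]) -> pd.DataFrame:
    """Descriptive statistics for each trait, one row per trait (raw scale)."""
    rows = []
    for spec in specs:
        st = descriptive_stats(table[spec.name])
        rows.append({
            "Trait": spec.name, "Unit": spec.unit, "N": st.n,
            "Mean": st.mean, "SD": st.sd, "Minimum": st.min,
            "Maximum": st.max, "CV%": st.cv_percent,
        })
    return pd.DataFrame(rows)
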