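"""QTL-detection power for an F2 intercross, plus liability-scale conversion.

A QTL explaining a fraction p of the phenotypic variance gives an (asymptotic)
likelihood-ratio noncentrality of n p / (1 - p) in an F2 of size n.  The
statistic is chi-square with 1 df (additive) or 2 df (additive + dominance).
Imperfect marker coverage attenuates the signal: with markers every s cM the
worst-case QTL sits mid-interval, and under the Haldane map function the
association decays by (1 - 2r)^2 at recombination fraction r, i.e. by
exp(-2 s / 100).  Genome-wide control uses a Sidak correction over an
effective number of independent tests of genome_length / spacing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import integrate, stats


@dataclasses.dataclass(frozen=True)
class PowerQuery:
    """Assumptions of one power calculation.

    ``var_fraction`` is the proportion of *phenotypic* variance explained by
    the QTL; set ``fraction_is_genetic`` when quoting a fraction of the
    genetic variance instead (it is multiplied by ``heritability``).
    Defaults: genome-wide alpha 0.05 over a 2300 cM, 18-autosome pig map at
    1 cM marker spacing.
    """

    n: int
    var_fraction: float
    heritability: float = 1.0
    fraction_is_genetic: bool = False
    marker_spacing_cm: float = 1.0
    alpha: float = 0.05
    genomewide: bool = True
    genome_length_cm: float = 2300.0
    chromosomes: int = 18
    dominance: bool = False

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not (0.0 <= self.var_fraction):
            raise ValueError("var_fraction must be non-negative")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        p = self.phenotypic_fraction
        if p >= 1.0:
            raise ValueError("QTL variance fraction must be below 1")

    @property
    def phenotypic_fraction(self) -> float:
        p = self.var_fraction
        if self.fraction_is_genetic:
            p = p * self.heritability
        return p


@dataclasses.dataclass(frozen=True)
class PowerResult:
    power: float
    noncentrality: float
    threshold: float
    df: int
    pointwise_alpha: float


def _effective_tests(q: PowerQuery) -> float:
    return max(1.0, q.genome_length_cm / q.marker_spacing_cm)


def f2_qtl_power(q: PowerQuery) -> PowerResult:
    """Detection power of a single QTL in an F2 of size ``q.n``."""
    p = q.phenotypic_fraction
    lam = q.n * p / (1.0 - p)
    # expected attenuation mid-interval under the Haldane map
    lam *= np.exp(-2.0 * q.marker_spacing_cm / 100.0)
    df = 2 if q.dominance else 1
    if q.genomewide:
        m = _effective_tests(q)
        alpha_point = 1.0 - (1.0 - q.alpha) ** (1.0 / m)
    else:
        alpha_point = q.alpha
    threshold = float(stats.chi2.isf(alpha_point, df))
    power = float(stats.ncx2.sf(threshold, df, lam)) if lam > 0 \
        else float(alpha_point)
    return PowerResult(power=power, noncentrality=float(lam),
                       threshold=threshold, df=df,
                       pointwise_alpha=float(alpha_point))


def f2_sample_size(target_power: float, q: PowerQuery,
                   n_max: int = 1_000_000) -> int:
    """Smallest F2 size reaching ``target_power`` under the query's assumptions."""
    if not (0.0 < target_power < 1.0):
        raise ValueError("target power must be in (0, 1)")

    def power_at(n: int) -> float:
        return f2_qtl_power(dataclasses.replace(q, n=n)).power

    lo, hi = 10, 10
    while power_at(hi) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(
                f"power {target_power} unreachable below n = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def liability_scale_h2(h2_observed: float, prevalence: float) -> float:
    """Dempster-Lerner conversion of an observed-scale (0/1) heritability.

    h2_liab = h2_obs * p (1 - p) / z^2, with z the standard-normal density
    at the threshold corresponding to prevalence p.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be strictly between 0 and 1")
    thresh = stats.norm.isf(prevalence)
    z = stats.norm.pdf(thresh)
    return h2_observed * prevalence * (1.0 - prevalence) / z**2


def liability_factor_quadrature(prevalence: float) -> float:
    """p(1-p)/z^2 via numeric integration of the threshold model (test oracle).

    The regression of the 0/1 trait on liability has slope
    E[x | x > t] * p / Var... reduced: cov(y, l) = E[l 1{l>t}] = z, so the
    observed-scale additive variance of a liability effect a is (a z / 1)^2
    against binary variance p(1-p); the factor is their ratio's inverse.
    Computed here from integrals rather than the closed form.
    """
    t = stats.norm.isf(prevalence)
    z_num, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), t, 12.0)
    p_num, _ = integrate.quad(stats.norm.pdf, t, 12.0)
    return p_num * (1.0 - p_num) / z_num**2


def monte_carlo_power(
    n: int,
    var_fraction: float,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
    dominance: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo rejection rate of the single-locus test at the QTL.

    Simulates F2 genotypes (allele counts Binomial(2, 1/2)), an additive QTL
    explaining ``var_fraction`` of the phenotypic variance, and the pointwise
    likelihood-ratio test; returns (rate, MC standard error).  Serves as the
    simulation oracle for :func:`f2_qtl_power` at zero marker distance.
    """
    rng = np.random.default_rng(seed)
    p = var_fraction
    a = np.sqrt(2 * p / (1 - p)) if p > 0 else 0.0   # var(additive score)=0.5
    df = 2 if dominance else 1
    thresh = stats.chi2.isf(alpha, df)
    rejections = 0
    for _ in range(n_sims):
        x = rng.binomial(2, 0.5, size=n).astype(float)
        y = a * (x - 1.0) + rng.standard_normal(n)
        X0 = np.ones((n, 1))
        cols = [np.ones(n), x - 1.0]
        if dominance:
            cols.append((x == 1).astype(float))
        X1 = np.column_stack(cols)
        r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
        lrt = n * np.log((r0 @ r0) / (r1 @ r1))
        rejections += lrt > thresh
    rate = rejections / n_sims
    return float(rate), float(np.sqrt(rate * (1 - rate) / n_sims))
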