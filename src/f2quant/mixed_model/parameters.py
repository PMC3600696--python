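"""Genetic parameters derived from (co)variance components, with delta-method SEs."""

from __future__ import annotations

import dataclasses

import numpy as np

from .reml import BivariateComponents, VarianceComponents


@dataclasses.dataclass
class GeneticParameters:
    h2: float
    h2_se: float
    rg: float | None = None
    rg_se: float | None = None
    rp: float | None = None
    rp_se: float | None = None
    source: str = "univariate"


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """h2 = sigma2_a / (sigma2_a + sigma2_e) with a first-order delta SE."""
    a, e = vc.sigma2_a, vc.sigma2_e
    s = a + e
    if s <= 0:
        raise ValueError("total variance is zero")
    h2 = a / s
    grad = np.array([e, -a]) / s**2
    return float(h2), _delta_se(grad, vc.sampling_cov)


def heritabilities_bivariate(bc: BivariateComponents) -> list[tuple[float, float]]:
    """Per-trait h2 (and SE) implied by a bivariate fit."""
    th = bc.theta
    cov = bc.sampling_cov
    out = []
    for (ia, ie) in ((0, 3), (2, 5)):
        a, e = th[ia], th[ie]
        s = a + e
        h2 = a / s
        grad = np.zeros(6)
        grad[ia] = e / s**2
        grad[ie] = -a / s**2
        out.append((float(h2), _delta_se(grad, cov)))
    return out


def correlations(bc: BivariateComponents):
    """Genetic and phenotypic correlations with delta-method SEs.

    rg = g12 / sqrt(g11 g22); rp = (g12 + r12) / sqrt(p1 p2) with
    p_t = g_tt + r_tt.  Returns ((rg, rg_se), (rp, rp_se)); rg is None when
    either genetic variance sits at zero.
    """
    g11, g12, g22, r11, r12, r22 = bc.theta
    cov = bc.sampling_cov

    if g11 <= 0 or g22 <= 0:
        rg_pair = (None, None)
    else:
        rg = g12 / np.sqrt(g11 * g22)
        grad = np.array([-rg / (2 * g11), 1.0 / np.sqrt(g11 * g22),
                         -rg / (2 * g22), 0.0, 0.0, 0.0])
        rg_pair = (float(rg), _delta_se(grad, cov))

    p1, p2 = g11 + r11, g22 + r22
    rp = (g12 + r12) / np.sqrt(p1 * p2)
    grad = np.array([-rp / (2 * p1), 1.0 / np.sqrt(p1 * p2), -rp / (2 * p2),
                     -rp / (2 * p1), 1.0 / np.sqrt(p1 * p2), -rp / (2 * p2)])
    rp_pair = (float(rp), _delta_se(grad, cov))
    return rg_pair, rp_pair


def select_heritability(
    univariate: GeneticParameters,
    bivariates: list[GeneticParameters],
) -> GeneticParameters:
    """Pick the heritability with the smallest standard error.

    Candidates with missing SEs are skipped; exact ties go to the univariate
    estimate.
    """
    candidates = [c for c in [univariate, *bivariates]
                  if c is not None and np.isfinite(c.h2_se)]
    if not candidates:
        raise ValueError("no converged heritability candidate")
    best = min(candidates, key=lambda c: c.h2_se)
    if univariate in candidates and univariate.h2_se <= best.h2_se:
        return univariate
    return best
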