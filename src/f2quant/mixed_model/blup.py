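"""Mixed-model equations: BLUE fixed effects, BLUP breeding values, PEV.

Henderson's mixed-model equations at the REML variance estimates give
predicted breeding values for every pedigree animal — phenotyped or not —
with prediction-error variances from the inverse coefficient matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from ..pedigree import RelationshipMatrix, a_inverse
from .design import DesignSystem


def _ainv_dense(ds: DesignSystem, A: RelationshipMatrix) -> np.ndarray:
    if A.Ainv is not None:
        return np.asarray(A.Ainv.todense())
    return a_inverse(ds.ped).Ainv.toarray()


def solve_mme(
    ds: DesignSystem,
    A: RelationshipMatrix,
    components,
    compute_pev: bool = True,
):
    """Solve the MME for a univariate or bivariate fit.

    Returns ``(ebv_frame, pev_frame, beta_dict)``; frames are indexed by
    pedigree animal id with one column per trait.
    """
    q = ds.ped.n
    Ainv = _ainv_dense(ds, A)
    t = len(ds.traits)

    if t == 1:
        td = ds.traits[0]
        vc = components
        n, p = td.X.shape
        Z = sparse.coo_matrix(
            (np.ones(n), (np.arange(n), td.animal_idx)), shape=(n, q)).tocsr()
        lam = vc.sigma2_e / max(vc.sigma2_a, 1e-300)
        Zd = Z.toarray()
        C = np.zeros((p + q, p + q))
        C[:p, :p] = td.X.T @ td.X
        C[:p, p:] = td.X.T @ Zd
        C[p:, :p] = C[:p, p:].T
        C[p:, p:] = Zd.T @ Zd + lam * Ainv
        rhs = np.concatenate([td.X.T @ td.y, Zd.T @ td.y])
        if compute_pev:
            Cinv = np.linalg.inv(C)
            sol = Cinv @ rhs
            pev = np.diag(Cinv)[p:] * vc.sigma2_e
        else:
            sol = np.linalg.solve(C, rhs)
            pev = None
        beta = {td.trait: dict(zip(td.x_names, sol[:p]))}
        ebv = pd.DataFrame({td.trait: sol[p:]},
                           index=[str(a) for a in ds.ped.ids])
        pev_frame = None if pev is None else pd.DataFrame(
            {td.trait: pev}, index=ebv.index)
        return ebv, pev_frame, beta

    # ---- bivariate ---------------------------------------------------------
    td1, td2 = ds.traits
    bc = components
    n1, n2 = len(td1.y), len(td2.y)
    N = n1 + n2
    p1, p2 = td1.X.shape[1], td2.X.shape[1]
    p = p1 + p2
    X = np.zeros((N, p))
    X[:n1, :p1] = td1.X
    X[n1:, p1:] = td2.X
    y = np.concatenate([td1.y, td2.y])

    # record -> u column (trait-major: trait 1 uses columns 0..q-1)
    Zd = np.zeros((N, 2 * q))
    Zd[np.arange(n1), td1.animal_idx] = 1.0
    Zd[n1 + np.arange(n2), q + td2.animal_idx] = 1.0

    # residual precision, per animal: 2x2 blocks where both traits recorded
    R = bc.R
    Rinv_full = np.linalg.inv(R)
    Oinv = np.zeros((N, N))
    rec1 = {a: i for i, a in enumerate(td1.animal_idx)}
    rec2 = {a: i for i, a in enumerate(td2.animal_idx)}
    both = set(rec1) & set(rec2)
    for a, i in rec1.items():
        if a not in both:
            Oinv[i, i] = 1.0 / R[0, 0]
    for a, j in rec2.items():
        if a not in both:
            Oinv[n1 + j, n1 + j] = 1.0 / R[1, 1]
    for a in both:
        i, j = rec1[a], n1 + rec2[a]
        Oinv[i, i] += Rinv_full[0, 0]
        Oinv[j, j] += Rinv_full[1, 1]
        Oinv[i, j] += Rinv_full[0, 1]
        Oinv[j, i] += Rinv_full[1, 0]

    W = np.hstack([X, Zd])
    Ginv = np.linalg.inv(bc.G)
    penalty = np.zeros((p + 2 * q, p + 2 * q))
    penalty[p:, p:] = np.kron(Ginv, Ainv)
    C = W.T @ Oinv @ W + penalty
    rhs = W.T @ (Oinv @ y)
    if compute_pev:
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        pev_diag = np.diag(Cinv)[p:]
        pev_frame = pd.DataFrame(
            {td1.trait: pev_diag[:q], td2.trait: pev_diag[q:]},
            index=[str(a) for a in ds.ped.ids])
    else:
        sol = np.linalg.solve(C, rhs)
        pev_frame = None
    beta = {td1.trait: dict(zip(td1.x_names, sol[:p1])),
            td2.trait: dict(zip(td2.x_names, sol[p1:p]))}
    u = sol[p:]
    ebv = pd.DataFrame({td1.trait: u[:q], td2.trait: u[q:]},
                       index=[str(a) for a in ds.ped.ids])
    return ebv, pev_frame, beta


def predict_ebv(fit, bins: int = 30):
    """EBV table for all pedigree animals plus histogram bin data per trait.

    Returns ``(ebv_frame, {trait: (bin_edges, counts)})`` suitable for
    plotting EBV distributions.
    """
    if fit.ebv is None:
        raise ValueError("fit was computed with compute_ebv=False")
    hists = {}
    for col in fit.ebv.columns:
        counts, edges = np.histogram(fit.ebv[col].to_numpy(), bins=bins)
        hists[col] = (edges, counts)
    return fit.ebv, hists
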