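"""Univariate and bivariate animal-model REML.

The variance structure is the classic animal model: phenotypes carry an
additive genetic effect with covariance ``A sigma2_a`` (A the pedigree
relationship matrix) and an independent residual.  Estimation maximises the
REML log-likelihood

    l = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

with a guaranteed-ascent EM-REML warm start followed by average-information
(AI) updates; any AI step that would leave the feasible region or decrease
the likelihood is halved repeatedly, then replaced by one EM step.

Both engines exploit the spectral trick: rotating records by the
eigenvectors of the relationship submatrix among phenotyped animals makes V
(block-)diagonal, so every iteration is O(n) after one eigendecomposition.
The bivariate model falls back to a dense-matrix path when the two traits
are recorded on different animal sets.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

from ..pedigree import RelationshipMatrix
from .design import DesignSystem

_E1 = np.array([[1.0, 0.0], [0.0, 0.0]])
_E2 = np.array([[0.0, 1.0], [1.0, 0.0]])
_E3 = np.array([[0.0, 0.0], [0.0, 1.0]])


@dataclasses.dataclass
class REMLOptions:
    em_iterations: int = 5
    max_iterations: int = 200
    tol_loglik: float = 1e-9
    tol_param: float = 1e-6
    variance_floor: float = 1e-6     # times the phenotypic variance
    max_halvings: int = 10
    min_residual_overlap: int = 10   # animals needed to estimate sigma_e12
    compute_ebv: bool = True
    compute_pev: bool = True


@dataclasses.dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    sampling_cov: np.ndarray         # 2x2, order (sigma2_a, sigma2_e)
    loglik: float
    converged: bool
    boundary: bool
    trace: list

    @property
    def phenotypic_variance(self) -> float:
        return self.sigma2_a + self.sigma2_e


@dataclasses.dataclass
class BivariateComponents:
    G: np.ndarray                    # 2x2 genetic covariance
    R: np.ndarray                    # 2x2 residual covariance
    sampling_cov: np.ndarray         # 6x6, order (g11,g12,g22,r11,r12,r22)
    loglik: float
    converged: bool
    boundary: bool
    residual_cov_estimated: bool
    trace: list

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.G[0, 0], self.G[0, 1], self.G[1, 1],
                         self.R[0, 0], self.R[0, 1], self.R[1, 1]])


@dataclasses.dataclass
class ModelFit:
    beta: dict                        # trait -> {name: estimate}
    ebv: "pd.DataFrame | None"        # per pedigree animal, one column per trait
    pev: "pd.DataFrame | None"
    components: "VarianceComponents | BivariateComponents"
    design: DesignSystem


# ---------------------------------------------------------------------------
# univariate engine (rotated coordinates)


class _UniState:
    """REML quantities at one parameter value, in rotated coordinates."""

    __slots__ = ("loglik", "grad", "ai", "beta", "Py_rot")

    def __init__(self, theta, d, ys, Xs):
        va, ve = theta
        v = va * d + ve
        w = 1.0 / v
        Xw = Xs * w[:, None]
        C = Xs.T @ Xw
        rhs = Xw.T @ ys
        cf = linalg.cho_factor(C)
        beta = linalg.cho_solve(cf, rhs)
        r = ys - Xs @ beta
        z = w * r                      # P y in rotated coordinates
        n = len(ys)
        _, logdetC = np.linalg.slogdet(C)
        self.loglik = -0.5 * (np.log(v).sum() + logdetC + float(r @ z))
        self.beta = beta
        self.Py_rot = z

        grads = np.empty(2)
        tk = [d * z, z]                # V_k P y for V_1 = diag(d), V_2 = I
        for k, dk in enumerate((d, np.ones(n))):
            tr_ViVk = float((dk * w).sum())
            Mk = Xw.T @ (dk[:, None] * Xw)
            tr_corr = float(np.trace(linalg.cho_solve(cf, Mk)))
            yPVPy = float(z @ (dk * z))
            grads[k] = -0.5 * ((tr_ViVk - tr_corr) - yPVPy)
        self.grad = grads

        ai = np.empty((2, 2))
        Pt = []
        for t in tk:
            u = Xw.T @ t
            Pt.append(w * t - Xw @ linalg.cho_solve(cf, u))
        for k in range(2):
            for l in range(2):
                ai[k, l] = 0.5 * float(tk[k] @ Pt[l])
        self.ai = 0.5 * (ai + ai.T)


def _maximise(theta0, state_fn, floors, opts, n_params):
    """Shared EM warm start + AI ascent with step halving.

    ``state_fn(theta)`` returns an object with .loglik, .grad, .ai.  The EM
    phase uses an exact monotone update when the engine provides one
    (``state_fn.em_update``); the univariate engine's scaled-gradient
    identity  theta_k += 2 theta_k^2 / n * g_k  is that exact update.  When
    neither an AI step nor a backtracking gradient step can increase the
    likelihood any further, the point is stationary and iteration stops.
    """
    theta = np.asarray(theta0, dtype=float)
    st = state_fn(theta)
    trace = [(0, st.loglik, theta.copy())]
    converged = False
    n_em = opts.em_iterations

    st_n = getattr(state_fn, "n_records", None)
    if st_n is None:
        raise RuntimeError("state_fn must expose n_records")

    def project(t):
        t = np.where(np.isfinite(floors), np.maximum(t, floors), t)
        return state_fn.project(t) if hasattr(state_fn, "project") else t

    def evaluate(cand):
        if hasattr(state_fn, "feasible") and not state_fn.feasible(cand):
            return None
        try:
            return state_fn(cand)
        except np.linalg.LinAlgError:
            return None

    def em_step(theta, st):
        if hasattr(state_fn, "em_update"):   # exact (monotone) matrix EM
            return project(state_fn.em_update(theta, st)), True
        if np.all(np.isfinite(floors)):      # variance-only: exact EM
            return project(theta + 2.0 * theta**2 / st_n * st.grad), True
        return None, False

    def backtrack_gradient(theta, st):
        """Ascent-guaranteed diagonally-scaled gradient step (or None)."""
        direction = st.grad / (np.abs(np.diag(st.ai)) + 1e-12)
        step = 1.0
        for _ in range(25):
            cand_st = evaluate(project(theta + step * direction))
            if cand_st is not None and cand_st.loglik > st.loglik:
                return project(theta + step * direction), cand_st
            step *= 0.5
        return None, None

    it = 0
    last_dll = None
    while it < opts.max_iterations:
        it += 1
        new_theta = new_st = None
        if it <= n_em:
            cand, ok = em_step(theta, st)
            if ok:
                new_theta, new_st = cand, state_fn(cand)
            else:
                new_theta, new_st = backtrack_gradient(theta, st)
                if new_theta is None:
                    converged = bool(last_dll is not None and abs(last_dll) < 1e-6)
                    break
        else:
            try:
                delta = np.linalg.solve(st.ai, st.grad)
            except np.linalg.LinAlgError:
                delta = st.grad / (np.diag(st.ai) + 1e-8)
            step = 1.0
            for _ in range(opts.max_halvings):
                cand = project(theta + step * delta)
                cand_st = evaluate(cand)
                if cand_st is not None and cand_st.loglik >= st.loglik - 1e-10:
                    new_theta, new_st = cand, cand_st
                    break
                step *= 0.5
            if new_theta is None:            # fall back to one monotone step
                cand, ok = em_step(theta, st)
                if ok:
                    new_theta, new_st = cand, state_fn(cand)
                else:
                    new_theta, new_st = backtrack_gradient(theta, st)
                if new_theta is None:        # no ascent at this resolution
                    converged = bool(last_dll is not None and abs(last_dll) < 1e-6)
                    break

        d_ll = new_st.loglik - st.loglik
        last_dll = d_ll
        denom = np.maximum(np.abs(theta), 1e-12)
        d_par = float(np.max(np.abs(new_theta - theta) / denom))
        theta, st = new_theta, new_st
        trace.append((it, st.loglik, theta.copy()))
        if it > n_em and abs(d_ll) < opts.tol_loglik * max(1.0, abs(st.loglik)) \
                and d_par < opts.tol_param:
            converged = True
            break
    return theta, st, trace, converged


def reml_univariate(
    ds: DesignSystem,
    A: RelationshipMatrix,
    options: REMLOptions | None = None,
) -> tuple[VarianceComponents, ModelFit]:
    """Fit the univariate animal model by EM+AI REML.

    ``A`` must carry the dense relationship matrix over the pedigree the
    design refers to.  Non-convergence and boundary estimates are flagged on
    the result, never raised.
    """
    opts = options or REMLOptions()
    if ds.is_pair:
        raise ValueError("use reml_bivariate for trait pairs")
    td = ds.traits[0]
    if A.A is None:
        raise ValueError("RelationshipMatrix.A required")
    K = A.A[np.ix_(td.animal_idx, td.animal_idx)]
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    ys = U.T @ td.y
    Xs = U.T @ td.X
    n, p = Xs.shape

    beta_ols, rss, *_ = np.linalg.lstsq(td.X, td.y, rcond=None)
    resid = td.y - td.X @ beta_ols
    varp = float(resid @ resid) / max(n - p, 1)
    floor = opts.variance_floor * varp
    floors = np.array([floor, floor])

    def state_fn(theta):
        return _UniState(theta, d, ys, Xs)
    state_fn.n_records = n

    theta0 = np.array([0.5 * varp, 0.5 * varp])
    theta, st, trace, converged = _maximise(theta0, state_fn, floors, opts, 2)

    boundary = bool(theta[0] <= floor * (1 + 1e-6))
    ai = st.ai
    try:
        sampling_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        sampling_cov = np.linalg.pinv(ai)
    vc = VarianceComponents(
        sigma2_a=float(theta[0]), sigma2_e=float(theta[1]),
        sampling_cov=sampling_cov, loglik=float(st.loglik),
        converged=converged, boundary=boundary, trace=trace)

    beta = {td.trait: dict(zip(td.x_names, st.beta))}
    fit = ModelFit(beta=beta, ebv=None, pev=None, components=vc, design=ds)
    if opts.compute_ebv:
        from .blup import solve_mme
        fit.ebv, fit.pev, fit.beta = solve_mme(
            ds, A, vc, compute_pev=opts.compute_pev)
    return vc, fit


# ---------------------------------------------------------------------------
# bivariate engines


class _BivFastState:
    """Per-animal 2x2 block REML quantities (identical record sets)."""

    __slots__ = ("loglik", "grad", "ai", "beta", "z", "Sinv", "H", "Cinv", "W")

    def __init__(self, theta, d, Yt, Xt, active):
        G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        n = len(d)
        S = d[:, None, None] * G + R
        det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
        if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
            raise np.linalg.LinAlgError("V not positive definite")
        Sinv = np.empty_like(S)
        Sinv[:, 0, 0] = S[:, 1, 1] / det
        Sinv[:, 1, 1] = S[:, 0, 0] / det
        Sinv[:, 0, 1] = Sinv[:, 1, 0] = -S[:, 0, 1] / det
        H = np.einsum("nij,njp->nip", Sinv, Xt)
        C = np.einsum("nip,niq->pq", Xt, H)
        rhs = np.einsum("nip,ni->p", H, Yt)
        cf = linalg.cho_factor(C)
        beta = linalg.cho_solve(cf, rhs)
        r = Yt - np.einsum("nip,p->ni", Xt, beta)
        z = np.einsum("nij,nj->ni", Sinv, r)
        _, logdetC = np.linalg.slogdet(C)
        self.loglik = -0.5 * (np.log(det).sum() + logdetC
                              + float(np.einsum("ni,ni->", r, z)))
        self.beta = beta
        self.z = z
        self.Sinv = Sinv
        self.H = H
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]))
        self.Cinv = Cinv
        self.W = np.einsum("nip,pq,njq->nij", H, Cinv, H)

        ones = np.ones(n)
        scales = (d, d, d, ones, ones, ones)
        Es = (_E1, _E2, _E3, _E1, _E2, _E3)
        grad = np.zeros(6)
        tvecs = []
        for k in range(6):
            c, E = scales[k], Es[k]
            if k not in active:
                tvecs.append(np.zeros_like(z))
                continue
            trSinvE = np.einsum("nij,ij->n", Sinv, E)
            T1 = float(c @ trSinvE)
            Mk = np.einsum("n,nip,ij,njq->pq", c, H, E, H)
            T2 = float(np.einsum("pq,qp->", Cinv, Mk))
            t = c[:, None] * np.einsum("ij,nj->ni", E, z)
            tvecs.append(t)
            yPVPy = float(np.einsum("ni,ni->", z, t))
            grad[k] = -0.5 * ((T1 - T2) - yPVPy)
        self.grad = grad

        ai = np.zeros((6, 6))
        Pts = []
        for t in tvecs:
            u = np.einsum("nip,ni->p", H, t)
            Pt = np.einsum("nij,nj->ni", Sinv, t) \
                - np.einsum("nip,p->ni", H, Cinv @ u)
            Pts.append(Pt)
        for k in active:
            for l in active:
                ai[k, l] = 0.5 * float(np.einsum("ni,ni->", tvecs[k], Pts[l]))
        for k in range(6):
            if k not in active:
                ai[k, k] = 1.0
        self.ai = 0.5 * (ai + ai.T)


def _theta_to_mats(theta):
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return G, R


def _psd_feasible(theta, floors):
    G, R = _theta_to_mats(theta)
    if theta[0] < floors[0] or theta[2] < floors[2]:
        return False
    if theta[3] <= 0 or theta[5] <= 0:
        return False
    if np.min(np.linalg.eigvalsh(G)) < -1e-12:
        return False
    if np.min(np.linalg.eigvalsh(R)) <= 0:
        return False
    return True


def _project_psd(theta, floors):
    """Clip covariances so G is PSD and R is PD, variances at their floors."""
    t = theta.copy()
    t[0] = max(t[0], floors[0])
    t[2] = max(t[2], floors[2])
    t[3] = max(t[3], floors[3])
    t[5] = max(t[5], floors[5])
    gmax = 0.999 * np.sqrt(t[0] * t[2])
    t[1] = float(np.clip(t[1], -gmax, gmax))
    rmax = 0.999 * np.sqrt(t[3] * t[5])
    t[4] = float(np.clip(t[4], -rmax, rmax))
    return t


def _bivariate_fast(td1, td2, K, opts, estimate_re_cov):
    """Both traits recorded on the same animals: rotated per-block engine."""
    order = np.argsort(td1.animal_idx)
    a1 = td1.animal_idx[order]
    order2 = np.argsort(td2.animal_idx)
    assert np.array_equal(a1, td2.animal_idx[order2])
    y1, X1 = td1.y[order], td1.X[order]
    y2, X2 = td2.y[order2], td2.X[order2]

    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    n = len(d)
    p1, p2 = X1.shape[1], X2.shape[1]
    Y = np.column_stack([y1, y2])
    Xb = np.zeros((n, 2, p1 + p2))
    Xb[:, 0, :p1] = X1
    Xb[:, 1, p1:] = X2
    Yt = U.T @ Y
    Xt = np.tensordot(U.T, Xb, axes=(1, 0))

    varp = np.empty(2)
    for j, (yv, Xv) in enumerate(((y1, X1), (y2, X2))):
        b, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        r = yv - Xv @ b
        varp[j] = float(r @ r) / max(len(yv) - Xv.shape[1], 1)
    fl = opts.variance_floor
    floors = np.array([fl * varp[0], -np.inf, fl * varp[1],
                       fl * varp[0], -np.inf, fl * varp[1]])
    cov_p = float(np.cov(y1, y2)[0, 1]) if estimate_re_cov else 0.0
    theta0 = np.array([0.5 * varp[0], 0.25 * cov_p, 0.5 * varp[1],
                       0.5 * varp[0], 0.25 * cov_p, 0.5 * varp[1]])
    active = set(range(6)) if estimate_re_cov else {0, 1, 2, 3, 5}

    def state_fn(theta):
        return _BivFastState(theta, d, Yt, Xt, active)
    state_fn.n_records = 2 * n
    state_fn.feasible = lambda t: _psd_feasible(t, floors)
    state_fn.project = lambda t: _project_psd(t, floors)

    def em_update(theta, st):
        """Exact EM-REML M-step on the per-animal sufficient statistics.

        G+ = mean_i [ d_i G z_i z_i' G + G - d_i G P_ii G ],
        R+ = mean_i [ R z_i z_i' R + R - R P_ii R ],
        with P_ii the i-th diagonal block of the projection matrix; both
        updates are guaranteed not to decrease the REML log-likelihood.
        """
        G, R = _theta_to_mats(theta)
        Pii = st.Sinv - st.W
        zz = np.einsum("ni,nj->nij", st.z, st.z)
        Gn = G @ np.einsum("n,nij->ij", d, zz - Pii) @ G / n + G
        Rn = R @ (zz.sum(axis=0) - Pii.sum(axis=0)) @ R / n + R
        Gn = 0.5 * (Gn + Gn.T)
        Rn = 0.5 * (Rn + Rn.T)
        new = np.array([Gn[0, 0], Gn[0, 1], Gn[1, 1],
                        Rn[0, 0], Rn[0, 1], Rn[1, 1]])
        if 4 not in active:
            new[4] = 0.0
        return _project_psd(new, floors)
    state_fn.em_update = em_update

    return _maximise(theta0, state_fn, floors, opts, 6), floors, (U, d)


class _BivDenseState:
    """General dense-matrix engine for arbitrary missing-record patterns."""

    __slots__ = ("loglik", "grad", "ai", "beta", "Py")

    def __init__(self, theta, parts, active):
        y, X, Vks, n = parts["y"], parts["X"], parts["Vk"], parts["n"]
        V = sum(theta[k] * Vks[k] for k in range(6))
        cf = linalg.cho_factor(V)
        Vinv_y = linalg.cho_solve(cf, y)
        Vinv_X = linalg.cho_solve(cf, X)
        C = X.T @ Vinv_X
        cfc = linalg.cho_factor(C)
        beta = linalg.cho_solve(cfc, X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ beta
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        _, logdetC = np.linalg.slogdet(C)
        self.loglik = -0.5 * (logdetV + logdetC + float(y @ Py))
        self.beta = beta
        self.Py = Py

        Vinv = linalg.cho_solve(cf, np.eye(n))
        P = Vinv - Vinv_X @ linalg.cho_solve(cfc, Vinv_X.T)
        grad = np.zeros(6)
        tvecs = []
        for k in range(6):
            if k not in active:
                tvecs.append(np.zeros(n))
                continue
            trPVk = float(np.einsum("ij,ji->", P, Vks[k]))
            t = Vks[k] @ Py
            tvecs.append(t)
            grad[k] = -0.5 * (trPVk - float(Py @ t))
        self.grad = grad
        ai = np.zeros((6, 6))
        Pts = [P @ t for t in tvecs]
        for k in active:
            for l in active:
                ai[k, l] = 0.5 * float(tvecs[k] @ Pts[l])
        for k in range(6):
            if k not in active:
                ai[k, k] = 1.0
        self.ai = 0.5 * (ai + ai.T)


def _bivariate_dense(td1, td2, A, opts, estimate_re_cov):
    K11 = A[np.ix_(td1.animal_idx, td1.animal_idx)]
    K22 = A[np.ix_(td2.animal_idx, td2.animal_idx)]
    K12 = A[np.ix_(td1.animal_idx, td2.animal_idx)]
    n1, n2 = len(td1.y), len(td2.y)
    n = n1 + n2
    J12 = (td1.animal_idx[:, None] == td2.animal_idx[None, :]).astype(float)

    def pad(M11=None, M12=None, M22=None):
        out = np.zeros((n, n))
        if M11 is not None:
            out[:n1, :n1] = M11
        if M22 is not None:
            out[n1:, n1:] = M22
        if M12 is not None:
            out[:n1, n1:] = M12
            out[n1:, :n1] = M12.T
        return out

    Vks = [pad(M11=K11), pad(M12=K12), pad(M22=K22),
           pad(M11=np.eye(n1)), pad(M12=J12), pad(M22=np.eye(n2))]
    y = np.concatenate([td1.y, td2.y])
    X = np.zeros((n, td1.X.shape[1] + td2.X.shape[1]))
    X[:n1, :td1.X.shape[1]] = td1.X
    X[n1:, td1.X.shape[1]:] = td2.X

    varp = np.empty(2)
    for j, td in enumerate((td1, td2)):
        b, *_ = np.linalg.lstsq(td.X, td.y, rcond=None)
        r = td.y - td.X @ b
        varp[j] = float(r @ r) / max(len(td.y) - td.X.shape[1], 1)
    fl = opts.variance_floor
    floors = np.array([fl * varp[0], -np.inf, fl * varp[1],
                       fl * varp[0], -np.inf, fl * varp[1]])
    theta0 = np.array([0.5 * varp[0], 0.0, 0.5 * varp[1],
                       0.5 * varp[0], 0.0, 0.5 * varp[1]])
    active = set(range(6)) if estimate_re_cov else {0, 1, 2, 3, 5}

    parts = {"y": y, "X": X, "Vk": Vks, "n": n}

    def state_fn(theta):
        return _BivDenseState(theta, parts, active)
    state_fn.n_records = n
    state_fn.feasible = lambda t: _psd_feasible(t, floors)
    state_fn.project = lambda t: _project_psd(t, floors)

    return _maximise(theta0, state_fn, floors, opts, 6), floors


def reml_bivariate(
    ds: DesignSystem,
    A: RelationshipMatrix,
    options: REMLOptions | None = None,
) -> tuple[BivariateComponents, ModelFit]:
    """Fit the bivariate animal model by EM+AI REML.

    The genetic covariance of the stacked animal effects is structured by
    the relationship matrix; the residual covariance is carried only by
    animals recording both traits.  When fewer than
    ``options.min_residual_overlap`` animals record both traits, the
    residual covariance is fixed at zero (with a warning).
    """
    opts = options or REMLOptions()
    if not ds.is_pair:
        raise ValueError("reml_bivariate needs a trait pair")
    if A.A is None:
        raise ValueError("RelationshipMatrix.A required")
    td1, td2 = ds.traits
    overlap = ds.overlap
    estimate_re_cov = len(overlap) >= opts.min_residual_overlap
    if not estimate_re_cov:
        warnings.warn(
            f"only {len(overlap)} animals record both traits; residual "
            "covariance fixed at 0", stacklevel=2)

    same_animals = (len(td1.animal_idx) == len(td2.animal_idx)
                    and set(td1.animal_idx) == set(td2.animal_idx))
    if same_animals:
        uniq = np.sort(np.unique(td1.animal_idx))
        K = A.A[np.ix_(uniq, uniq)]
        (theta, st, trace, converged), floors, _rot = _bivariate_fast(
            td1, td2, K, opts, estimate_re_cov)
    else:
        (theta, st, trace, converged), floors = _bivariate_dense(
            td1, td2, A.A, opts, estimate_re_cov)

    G, R = _theta_to_mats(theta)
    boundary = bool(theta[0] <= floors[0] * (1 + 1e-6)
                    or theta[2] <= floors[2] * (1 + 1e-6))
    # correlation pinned at the clip is a boundary solution too
    if theta[0] > 0 and theta[2] > 0:
        boundary |= bool(abs(theta[1]) >= 0.999 * np.sqrt(theta[0] * theta[2])
                         * (1 - 1e-9))
    try:
        sampling_cov = np.linalg.inv(st.ai)
    except np.linalg.LinAlgError:
        sampling_cov = np.linalg.pinv(st.ai)
    bc = BivariateComponents(
        G=G, R=R, sampling_cov=sampling_cov, loglik=float(st.loglik),
        converged=converged, boundary=boundary,
        residual_cov_estimated=estimate_re_cov, trace=trace)

    p1 = td1.X.shape[1]
    beta = {td1.trait: dict(zip(td1.x_names, st.beta[:p1])),
            td2.trait: dict(zip(td2.x_names, st.beta[p1:]))}
    fit = ModelFit(beta=beta, ebv=None, pev=None, components=bc, design=ds)
    if opts.compute_ebv:
        from .blup import solve_mme
        fit.ebv, fit.pev, fit.beta = solve_mme(
            ds, A, bc, compute_pev=opts.compute_pev)
    return bc, fit
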