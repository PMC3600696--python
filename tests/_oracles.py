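"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: relationships by
path counting over common ancestors (Wright's method), REML by brute-force
surface maximisation on the dense likelihood, derivatives by central
differences.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from f2quant.pedigree import Pedigree


def _paths_up(ped: Pedigree, i: int) -> list[tuple[int, ...]]:
    """All ancestor paths starting at i (inclusive), as node tuples."""
    out = []

    def rec(node, path):
        path = path + (node,)
        out.append(path)
        for p in (ped.sire[node], ped.dam[node]):
            if p != -1:
                rec(p, path)

    rec(i, ())
    return out


def path_counting_inbreeding(ped: Pedigree, i: int) -> float:
    s, d = ped.sire[i], ped.dam[i]
    if s == -1 or d == -1:
        return 0.0
    return 0.5 * path_counting_relationship(ped, s, d)


def path_counting_relationship(ped: Pedigree, i: int, j: int) -> float:
    """a_ij = sum over non-overlapping path pairs to common ancestors of
    0.5^(links) * (1 + F_ancestor);  a_ii = 1 + F_i."""
    if i == j:
        return 1.0 + path_counting_inbreeding(ped, i)
    total = 0.0
    for p1 in _paths_up(ped, i):
        set1 = set(p1)
        for p2 in _paths_up(ped, j):
            if p1[-1] != p2[-1]:
                continue
            if set1 & set(p2) != {p1[-1]}:
                continue
            links = (len(p1) - 1) + (len(p2) - 1)
            total += 0.5 ** links * (1.0 + path_counting_inbreeding(ped, p1[-1]))
    return total


def path_counting_A(ped: Pedigree) -> np.ndarray:
    n = ped.n
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = path_counting_relationship(ped, i, j)
    return A


# ---------------------------------------------------------------------------


def dense_reml_loglik(y, X, K, va, ve) -> float:
    """REML log-likelihood from the dense V, no rotation tricks."""
    V = va * K + ve * np.eye(len(y))
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    signc, logdetC = np.linalg.slogdet(C)
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    r = y - X @ beta
    return float(-0.5 * (logdetV + logdetC + r @ Vinv @ r))


def brute_force_reml(y, X, K, grid: int = 200) -> tuple[float, float]:
    """Grid search plus Nelder-Mead refinement of the REML surface."""
    varp = float(np.var(y, ddof=1))
    vals = np.linspace(1e-4 * varp, 2.0 * varp, grid)
    best, best_ll = None, -np.inf
    for va in vals:
        for ve in vals:
            ll = dense_reml_loglik(y, X, K, va, ve)
            if ll > best_ll:
                best_ll, best = ll, (va, ve)
    res = optimize.minimize(
        lambda th: -dense_reml_loglik(y, X, K, abs(th[0]), abs(th[1])),
        x0=np.array(best), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return abs(res.x[0]), abs(res.x[1])


def numeric_gradient(fn, theta, h: float = 1e-6) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    g = np.zeros_like(theta)
    for k in range(len(theta)):
        up, dn = theta.copy(), theta.copy()
        step = h * max(1.0, abs(theta[k]))
        up[k] += step
        dn[k] -= step
        g[k] = (fn(up) - fn(dn)) / (2 * step)
    return g


def random_pedigree(rng, n_founders=10, n_gen=3, per_gen=30,
                    allow_inbreeding=True) -> Pedigree:
    """Random multi-generation pedigree for property tests."""
    from f2quant.pedigree import pedigree_from_records
    records = [(f"A{k}", None, None) for k in range(n_founders)]
    pool = [f"A{k}" for k in range(n_founders)]
    counter = n_founders
    for _g in range(n_gen):
        newborn = []
        for _ in range(per_gen):
            s, d = rng.choice(len(pool), size=2, replace=False)
            records.append((f"A{counter}", pool[s], pool[d]))
            newborn.append(f"A{counter}")
            counter += 1
        pool = newborn if not allow_inbreeding else pool + newborn
    return pedigree_from_records(records)


def random_animal_dataset(rng, n_animals=25, h2=0.5, n_fixed=2):
    """Small random dataset with a known relationship structure."""
    ped = random_pedigree(rng, n_founders=max(4, n_animals // 4), n_gen=2,
                          per_gen=max(3, n_animals // 3))
    from f2quant.pedigree import additive_relationship_matrix
    A = additive_relationship_matrix(ped).A
    idx = rng.choice(ped.n, size=min(n_animals, ped.n), replace=False)
    K = A[np.ix_(idx, idx)]
    n = len(idx)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, n_fixed - 1))])
    beta = rng.standard_normal(n_fixed)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    g = np.sqrt(h2) * (L @ rng.standard_normal(n))
    e = np.sqrt(1 - h2) * rng.standard_normal(n)
    y = X @ beta + g + e
    return y, X, K
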