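"""Independent numeric oracles used by the tests.

These deliberately avoid the eigenvalue algebra of the package: correlation
matrices are materialized densely, inverted numerically, and the expected
GLS information is obtained by brute-force enumeration of balanced
treatment allocations with the Gaussian expectation over the modifier taken
analytically (E[x'Mx] = tr(M S) + mu'M mu).  They are exact up to floating
point, so closed-form results can be checked to tight tolerances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dense_nested_exchangeable(n_s: int, m: int, a0: float, a1: float) -> np.ndarray:
    side = n_s * m
    out = np.full((side, side), a1)
    for j in range(n_s):
        out[j * m : (j + 1) * m, j * m : (j + 1) * m] = a0
    np.fill_diagonal(out, 1.0)
    return out


def _balanced_w_patterns(rand_level: str, n_s: int, m: int, alloc: float):
    """All equally likely centered treatment vectors for one cluster."""
    n = n_s * m
    if rand_level == "cluster":
        # treated with probability alloc, control otherwise
        yield alloc, np.full(n, 1.0 - alloc)
        yield 1.0 - alloc, np.full(n, -alloc)
        return
    if rand_level == "subcluster":
        k = round(n_s * alloc)
        combos = list(itertools.combinations(range(n_s), k))
        prob = 1.0 / len(combos)
        for treated in combos:
            w = np.full(n, -alloc)
            for j in treated:
                w[j * m : (j + 1) * m] = 1.0 - alloc
            yield prob, w
        return
    k = round(m * alloc)
    per_sub = list(itertools.combinations(range(m), k))
    prob = 1.0 / (len(per_sub) ** n_s)
    for assignment in itertools.product(per_sub, repeat=n_s):
        w = np.full(n, -alloc)
        for j, treated in enumerate(assignment):
            for t in treated:
                w[j * m + t] = 1.0 - alloc
        yield prob, w


def expected_information(
    rand_level: str,
    n_s: int,
    m: int,
    alloc: float,
    alpha0: float,
    alpha1: float,
    rho0: float,
    rho1: float,
    sigma2_x: float,
    mu_x: float,
) -> np.ndarray:
    """Per-cluster expected GLS information E[Z' R^{-1} Z] for the design
    columns (1, w, x, w*x), averaging exactly over balanced allocations and
    analytically over the Gaussian modifier."""
    n = n_s * m
    a = np.linalg.inv(dense_nested_exchangeable(n_s, m, alpha0, alpha1))
    s = sigma2_x * dense_nested_exchangeable(n_s, m, rho0, rho1)
    mu = np.full(n, mu_x)
    ones = np.ones(n)
    info = np.zeros((4, 4))
    for prob, w in _balanced_w_patterns(rand_level, n_s, m, alloc):
        cols = {"1": ones, "w": w}
        diags = {"x": np.ones(n), "wx": w}
        block = np.zeros((4, 4))
        keys = ["1", "w", "x", "wx"]
        for i, ki in enumerate(keys):
            for j, kj in enumerate(keys):
                if j < i:
                    continue
                if ki in cols and kj in cols:
                    val = cols[ki] @ a @ cols[kj]
                elif ki in cols:
                    dv = np.diag(diags[kj])
                    val = cols[ki] @ a @ dv @ mu
                elif kj in cols:
                    du = np.diag(diags[ki])
                    val = mu @ du @ a @ cols[kj]
                else:
                    du, dv = np.diag(diags[ki]), np.diag(diags[kj])
                    val = np.trace(du @ a @ dv @ s) + mu @ du @ a @ dv @ mu
                block[i, j] = block[j, i] = val
        info += prob * block
    return info


def oracle_hte_unit_variance(
    rand_level, n_s, m, alloc, alpha0, alpha1, rho0, rho1,
    sigma2_y=1.0, sigma2_x=1.0, mu_x=0.0,
) -> float:
    """n_s m * sigma_{y|x}^2 * [E-info^{-1}]_{interaction}."""
    info = expected_information(
        rand_level, n_s, m, alloc, alpha0, alpha1, rho0, rho1, sigma2_x, mu_x
    )
    return n_s * m * sigma2_y * np.linalg.inv(info)[3, 3]


def oracle_ate_unit_variance(
    rand_level, n_s, m, alloc, alpha0, alpha1, rho0, rho1,
    sigma2_y=1.0, sigma2_x=1.0,
) -> float:
    """Same, for the treatment coefficient with a centered modifier."""
    info = expected_information(
        rand_level, n_s, m, alloc, alpha0, alpha1, rho0, rho1, sigma2_x, 0.0
    )
    return n_s * m * sigma2_y * np.linalg.inv(info)[1, 1]


def dense_restricted_loglik(
    y: np.ndarray,
    z: np.ndarray,
    n_c: int,
    n_s: int,
    m: int,
    sigma2_gamma: float,
    sigma2_u: float,
    sigma2_eps: float,
) -> float:
    """REML log-likelihood via dense covariance matrices."""
    n = n_c * n_s * m
    q = z.shape[1]
    v_cluster = (
        sigma2_eps * np.eye(n_s * m)
        + sigma2_u * np.kron(np.eye(n_s), np.ones((m, m)))
        + sigma2_gamma * np.ones((n_s * m, n_s * m))
    )
    blocks = [v_cluster] * n_c
    v = np.zeros((n, n))
    for i, b in enumerate(blocks):
        sl = slice(i * n_s * m, (i + 1) * n_s * m)
        v[sl, sl] = b
    vinv = np.linalg.inv(v)
    info = z.T @ vinv @ z
    beta = np.linalg.solve(info, z.T @ vinv @ y)
    r = y - z @ beta
    _, logdet_v = np.linalg.slogdet(v)
    _, logdet_info = np.linalg.slogdet(info)
    return -0.5 * (
        (n - q) * math.log(2 * math.pi)
        + logdet_v
        + logdet_info
        + r @ vinv @ r
    )
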