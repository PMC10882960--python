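"""Independent oracles used by the test suite.

Everything here deliberately avoids the implementation paths it checks:
numerical integration instead of the Laplace formula, normal equations
instead of lstsq-based fitting, exhaustive vertex search instead of the LP.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from invacf.nbglmm import nb_loglik


def agq_marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    group_codes: list[np.ndarray],
    beta: np.ndarray,
    theta: float,
    sigmas: list[float],
    n_nodes: int = 21,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood at fixed parameters.

    Integrates the NB likelihood over all random intercepts (mode-centred,
    curvature-scaled tensor grid).  Total random-effect dimension must stay
    small (<= 6).
    """
    n_levels = [int(codes.max()) + 1 for codes in group_codes]
    dim = sum(n_levels)
    if dim > 6:
        raise ValueError("oracle limited to <= 6 random-effect dimensions")
    offsets = np.concatenate([[0], np.cumsum(n_levels)])[:-1]
    var = np.concatenate(
        [np.full(k, s**2) for k, s in zip(n_levels, sigmas)]
    )

    def joint(u: np.ndarray) -> float:
        eta = X @ beta
        for codes, off in zip(group_codes, offsets):
            eta = eta + u[off + codes]
        return float(
            nb_loglik(y, eta, theta)
            + np.sum(-0.5 * np.log(2 * np.pi * var) - 0.5 * u**2 / var)
        )

    res = minimize(lambda u: -joint(u), np.zeros(dim), method="BFGS")
    u_hat = res.x
    eps = 1e-4
    H = np.zeros((dim, dim))
    for a in range(dim):
        for b in range(dim):
            da = np.zeros(dim)
            db = np.zeros(dim)
            da[a] = eps
            db[b] = eps
            H[a, b] = -(
                joint(u_hat + da + db)
                - joint(u_hat + da - db)
                - joint(u_hat - da + db)
                + joint(u_hat - da - db)
            ) / (4 * eps * eps)
    L = np.linalg.cholesky(np.linalg.inv(H))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    grid = np.array(list(itertools.product(range(n_nodes), repeat=dim)))
    x = nodes[grid]
    W = weights[grid].prod(axis=1)
    U = u_hat + (math.sqrt(2) * x) @ L.T
    vals = np.array([joint(u) + np.sum(xi**2) for u, xi in zip(U, x)])
    mx = vals.max()
    return float(
        mx
        + math.log(np.sum(W * np.exp(vals - mx)))
        + 0.5 * dim * math.log(2)
        + math.log(abs(np.linalg.det(L)))
    )


def zero_intercept_quadratic_fit(money: np.ndarray, mass: np.ndarray) -> np.ndarray:
    """Normal-equations solution of mass = c1*money + c2*money^2."""
    A = np.column_stack([money, money**2])
    return np.linalg.solve(A.T @ A, A.T @ mass)


def quantile_vertex_search(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float
) -> tuple[float, float, float]:
    """Exhaustive search over point-pair basic solutions of the check loss.

    For a 2-parameter quantile regression an optimal line passes through at
    least two data points; enumerating all pairs and evaluating the weighted
    tilted loss finds the global optimum for small n.  Returns (intercept,
    slope, loss).
    """
    best = (math.nan, math.nan, math.inf)
    n = len(x)
    for a in range(n):
        for b in range(a + 1, n):
            if x[a] == x[b]:
                continue
            slope = (y[b] - y[a]) / (x[b] - x[a])
            intercept = y[a] - slope * x[a]
            r = y - intercept - slope * x
            loss = float(np.sum(w * np.where(r >= 0, tau * r, (tau - 1) * r)))
            if loss < best[2]:
                best = (intercept, slope, loss)
    return best


def brute_force_eligible_pairs(
    panel, horizon_years: int = 150, threshold: float = 100.0
) -> set[tuple[str, str]]:
    """Recount of the trade-rate filter straight from the panel rows."""
    last = int(panel["decade_end"].max())
    final = panel[panel["decade_end"] == last]
    out = set()
    for row in final.itertuples(index=False):
        if float(row.TR) / horizon_years >= threshold:
            out.add((str(row.e), str(row.i)))
    return out
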