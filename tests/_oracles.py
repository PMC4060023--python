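"""Independent optimization oracles used to certify the NNLS solver.

Kept deliberately separate from the package's active-set implementation:
the projected-gradient (FISTA) solver reaches the same optimum by a
different route, and the KKT check evaluates the optimality conditions
directly from the problem data.
"""

import numpy as np


def objective(A: np.ndarray, b: np.ndarray, x: np.ndarray) -> float:
    r = A @ x - b
    return 0.5 * float(r @ r)


def kkt_violation(
    A: np.ndarray, b: np.ndarray, x: np.ndarray, lam: float = 0.0
) -> float:
    """Max violation of the NNLS KKT conditions at x.

    Stationarity requires g = Aᵀ(Ax − b) + λ²x to vanish on strictly
    positive coordinates and be non-negative on zero coordinates.
    """
    g = A.T @ (A @ x - b) + lam**2 * x
    active = x <= 1e-12
    v_passive = float(np.abs(g[~active]).max(initial=0.0))
    v_active = float(np.maximum(-g[active], 0.0).max(initial=0.0))
    return max(v_passive, v_active)


def projected_gradient_nnls(
    A: np.ndarray,
    b: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 20_000,
) -> np.ndarray:
    """Accelerated projected gradient (FISTA with restart) for NNLS.

    The first-order iteration identifies the optimal support; once the KKT
    violation stalls, the coefficients on the strictly positive support are
    polished by a direct least-squares solve, accepted only if feasible and
    strictly better under the same KKT measure.
    """
    A = np.asarray(A, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = A.shape[1]
    L = np.linalg.norm(A, 2) ** 2
    if L == 0:
        return np.zeros(n)
    x = np.zeros(n)
    y = x.copy()
    t = 1.0
    for it in range(max_iter):
        if it % 25 == 0:
            v = kkt_violation(A, b, x)
            if v < tol:
                return x
            if it >= 500:
                break
        g = A.T @ (A @ y - b)
        x_new = np.maximum(y - g / L, 0.0)
        if objective(A, b, x_new) > objective(A, b, x):  # restart
            y = x.copy()
            t = 1.0
            continue
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
    # polish coefficients on the support found by the first-order method
    scale = max(float(x.max(initial=0.0)), 1.0)
    support = x > 1e-9 * scale
    if support.any():
        z, *_ = np.linalg.lstsq(A[:, support], b, rcond=None)
        if (z > 0).all():
            cand = np.zeros(n)
            cand[support] = z
            if kkt_violation(A, b, cand) < kkt_violation(A, b, x):
                return cand
    return x
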