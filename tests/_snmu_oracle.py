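"""Independent brute-force oracle for the rank-one underapproximation
subproblem: exhaustive grid search over simplex directions h (the optimal
feasible w is closed-form per row), refined by Nelder-Mead on the exact
objective.  Kept free of any code path shared with the package solver."""

import numpy as np
from scipy.optimize import minimize


def underapprox_objective(X: np.ndarray, h: np.ndarray) -> float:
    """Exact Frobenius reduction for direction ``h`` with the optimal
    feasible ``w`` (closed form per row)."""
    h = np.clip(np.asarray(h, dtype=float), 0.0, None)
    hh = h @ h
    if hh == 0:
        return 0.0
    w = np.clip(X @ h / hh, 0.0, None)
    sup = h > 0
    with np.errstate(divide="ignore", over="ignore"):
        bound = (X[:, sup] / h[sup]).min(axis=1)
    w = np.minimum(w, np.clip(bound, 0.0, None))
    P = np.outer(w, h)
    return 2.0 * (X * P).sum() - (P * P).sum()


def brute_force_rank_one(X: np.ndarray, step: float = 1.0 / 40) -> float:
    """Best objective over a discretised simplex of 3-vector directions,
    polished with Nelder-Mead."""
    best, best_h = 0.0, None
    grid = np.arange(0.0, 1.0 + 1e-9, step)
    for a in grid:
        for b in grid:
            if a + b > 1 + 1e-9:
                continue
            h = np.array([a, b, 1.0 - a - b])
            val = underapprox_objective(X, h)
            if val > best:
                best, best_h = val, h
    if best_h is not None:
        res = minimize(
            lambda v: -underapprox_objective(X, np.abs(v)),
            best_h, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        best = max(best, -res.fun)
    return best
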