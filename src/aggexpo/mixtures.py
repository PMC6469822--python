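"""Mixture prioritisation by sparse nonnegative matrix underapproximation
(SNMU) with maximum-cumulative-ratio (MCR) filtering.

The exposure matrix ``X`` (individuals x compounds, RPF-weighted, all
entries >= 0) is decomposed sequentially into rank-one nonnegative terms
``w h^T`` constrained to lie below the running residual elementwise (the
underapproximation constraint), deflating the residual after each term.  The
normalised ``h`` of each term gives the SNMU weights of one mixture — the
relative importance of each compound in a co-occurring exposure pattern —
and its variance explained is the share of the matrix's squared
Frobenius norm removed by the term, ||R||_F^2 - ||R - w h^T||_F^2 over
||X||_F^2 (raw, per-component convention; shares telescope, so they sum to
at most 1 and are non-increasing in rank when each term is optimal).

The rank-one subproblem min ||R - w h^T||_F^2 s.t. 0 <= w h^T <= R reduces
to a search over the compound direction ``h`` alone: for fixed ``h`` the
optimal feasible ``w`` is closed-form per row (the unconstrained
least-squares value capped at the row's underapproximation bound
min_j R_ij/h_j), and the resulting objective is invariant to the scale of
``h``.  The solver generates candidate directions with a Lagrangian phase —
the underapproximation constraint relaxed by multipliers updated with a
diminishing-step rule, Lam <- max(0, Lam - (R - w h^T)/(k+1)), alternating
nonnegative least-squares updates on the shifted matrix R - Lam — started
from the highest-norm residual columns, then polishes each candidate by
direct derivative-free maximisation of the exact constrained objective over
the simplex-normalised direction.  The final iterate is exactly feasible by
construction.  Sparsity is a post-fit relative threshold: compounds whose
weight falls below ``sparsity * max(weight)`` are zeroed and the term
refit, so ``sparsity = 0`` is exact and the convention is scale-invariant.
The whole procedure is deterministic; the seed only breaks exact ties.

MCR (cumulative exposure over maximum single-compound exposure, per
individual) quantifies how mixture-like an individual's exposure is;
filtering rows with MCR <= threshold before SNMU focuses the decomposition
on the subpopulation exposed to genuine mixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Mixture:
    """One ranked mixture: normalised SNMU weights per compound (descending),
    its variance-explained share, and raw exposure summaries of its
    component compounds over the reporting subpopulation."""

    rank: int
    components: list[tuple[str, float]]
    variance_explained: float
    summaries: pd.DataFrame | None = None  # per compound: mean, median, p5, p95

    def weights(self) -> dict[str, float]:
        return dict(self.components)


def compute_mcr(X: pd.DataFrame) -> pd.Series:
    """Maximum cumulative ratio per individual: row sum over row max.

    Defined for rows with positive total; zero rows get NaN.  Bounded below
    by 1 (single dominant compound) and above by the number of positive
    entries in the row.
    """
    M = X.to_numpy(dtype=float)
    if (M < 0).any():
        raise ValueError("exposure matrix must be nonnegative")
    rowsum = M.sum(axis=1)
    rowmax = M.max(axis=1) if M.size else np.zeros(len(X))
    if not (rowsum > 0).any():
        raise ValueError("all-zero exposure matrix: MCR undefined for every row")
    with np.errstate(invalid="ignore", divide="ignore"):
        mcr = np.where(rowsum > 0, rowsum / rowmax, np.nan)
    return pd.Series(mcr, index=X.index, name="mcr")


def _best_w(R: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Exact row-wise minimiser of ||R - w h^T||^2 s.t. w h^T <= R, w >= 0."""
    hh = float(h @ h)
    if hh == 0:
        return np.zeros(R.shape[0])
    w = np.clip(R @ h / hh, 0.0, None)
    sup = h > 0
    if sup.any():
        with np.errstate(divide="ignore", over="ignore"):
            bound = (R[:, sup] / h[sup]).min(axis=1)
        w = np.minimum(w, np.clip(bound, 0.0, None))
    return w


def _objective_h(R: np.ndarray, h: np.ndarray) -> float:
    """Frobenius reduction 2<R, wh^T> - ||wh^T||^2 at the optimal feasible
    ``w`` for direction ``h``; invariant to the scale of ``h``."""
    h = np.clip(h, 0.0, None)
    if h.max() <= 0:
        return 0.0
    w = _best_w(R, h)
    P = np.outer(w, h)
    return 2.0 * float((R * P).sum()) - float((P * P).sum())


def _lagrangian_candidates(R: np.ndarray, n_starts: int, n_iter: int):
    """Candidate directions from the relaxed (Lagrangian) alternation,
    started from the highest-norm columns of the residual."""
    col_norms = np.linalg.norm(R, axis=0)
    starts = np.argsort(-col_norms, kind="stable")[:n_starts]
    candidates = []
    for j in starts:
        if col_norms[j] == 0:
            continue
        e = np.zeros(R.shape[1])
        e[j] = 1.0
        candidates.append(e)  # the single-compound axis itself
        w = R[:, j].copy()
        h = e.copy()
        Lam = np.zeros_like(R)
        for k in range(1, n_iter + 1):
            A = R - Lam
            ww = float(w @ w)
            if ww == 0:
                break
            h = np.clip(A.T @ w / ww, 0.0, None)
            hh = float(h @ h)
            if hh == 0:
                break
            w = np.clip(A @ h / hh, 0.0, None)
            Lam = np.clip(Lam - (R - np.outer(w, h)) / (k + 1), 0.0, None)
        if h.max() > 0:
            candidates.append(h / h.sum())
    return candidates


def _polish(R: np.ndarray, h0: np.ndarray, max_iter: int, maxfev: int):
    """Derivative-free maximisation of the exact objective over the
    direction ``h``, started at ``h0`` (Powell direction-set search)."""
    from scipy.optimize import minimize

    def neg(v):
        return -_objective_h(R, np.abs(v))

    res = minimize(
        neg, h0, method="Powell",
        options={"maxiter": max_iter,
                 **({"maxfev": maxfev} if maxfev else {}),
                 "xtol": 1e-9, "ftol": 1e-12},
    )
    h = np.abs(res.x)
    if h.max() > 0:
        h = h / h.sum()
    return h, -res.fun, bool(res.success)


def _rank_one(R: np.ndarray, tol: float, max_iter: int, n_starts: int = 8,
              lagrangian_iters: int = 150, n_polish: int = 3):
    """Best rank-one underapproximation of ``R``: Lagrangian candidate
    directions, the best few polished by direct search over ``h``.

    Polish cost is bounded (``maxfev`` scales with the number of compounds)
    so the solver stays fast on survey-scale matrices; on small matrices the
    budget is effectively unconstrained.
    """
    m = R.shape[1]
    candidates = _lagrangian_candidates(R, n_starts, lagrangian_iters)
    scored = sorted(
        ((float(_objective_h(R, h0)), i, h0) for i, h0 in enumerate(candidates)),
        key=lambda t: (-t[0], t[1]),
    )
    # polish everything on small problems; on survey-scale matrices only the
    # most promising candidates, with a bounded evaluation budget
    small = R.size <= 20_000
    budget = len(scored) if small else n_polish
    maxfev = None if small else max(2000, 60 * m)
    best_h, best_obj = np.zeros(m), 0.0
    converged = len(scored) > 0
    for rank, (base, _, h0) in enumerate(scored):
        if rank < budget:
            h, obj, ok = _polish(R, h0, max_iter, maxfev)
            converged = converged and (ok or obj > base)
            if obj < base:  # never let the polish degrade its start
                h, obj = h0 / h0.sum(), base
        else:
            h, obj = h0 / h0.sum(), base
        if obj > best_obj * (1 + tol):
            best_h, best_obj = h, obj
    w = _best_w(R, best_h)
    return w, best_h, best_obj, converged


def snmu(
    X: pd.DataFrame,
    k: int = 3,
    sparsity: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 500,
    seed: int = 0,
) -> list[Mixture]:
    """Sequential rank-one SNMU of a nonnegative exposure matrix.

    Returns ``k`` mixtures; per rank the residual is deflated by the
    rank-one term (clipped at zero against floating-point dust).  Weights
    are the normalised ``h`` (summing to 1, sorted descending), after
    zeroing compounds below the relative ``sparsity`` threshold and
    refitting; ``variance_explained`` is the term's Frobenius-reduction
    share of ``||X||_F^2``.  Deterministic for fixed inputs; ``seed`` is
    accepted for interface symmetry and tie-breaking only.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError(f"sparsity must be in [0,1), got {sparsity}")
    M = X.to_numpy(dtype=float)
    if (M < 0).any():
        raise ValueError("exposure matrix must be nonnegative")
    norm2 = float((M * M).sum())
    if norm2 == 0:
        raise ValueError("all-zero exposure matrix")
    cols = list(X.columns)
    R = M.copy()
    mixtures = []
    for r in range(1, k + 1):
        w, h, obj, converged = _rank_one(R, tol, max_iter)
        if not converged:
            warnings.warn(
                f"SNMU rank {r}: direction search did not converge within "
                f"{max_iter} iterations; using last iterate",
                RuntimeWarning,
            )
        if sparsity > 0 and h.max() > 0:
            h = np.where(h >= sparsity * h.max(), h, 0.0)
            w = _best_w(R, h)  # refit on the sparsified support
        if h.sum() == 0:
            break
        hn = h / h.sum()
        comps = sorted(
            ((cols[j], float(hn[j])) for j in range(len(cols)) if hn[j] > 0),
            key=lambda t: (-t[1], t[0]),
        )
        P = np.outer(w, h)
        reduction = 2.0 * float((R * P).sum()) - float((P * P).sum())
        ve = reduction / norm2
        mixtures.append(Mixture(rank=r, components=comps, variance_explained=ve))
        R = np.clip(R - P, 0.0, None)
    return mixtures


def select_mixtures(
    X: pd.DataFrame,
    k: int = 3,
    sparsity: float = 0.05,
    mcr_threshold: float | None = 2.0,
    seed: int = 0,
    raw_exposure: pd.DataFrame | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> list[Mixture]:
    """MCR-filtered mixture selection with per-compound exposure summaries.

    Rows with MCR <= ``mcr_threshold`` are dropped before the decomposition
    (``None`` keeps all rows); component summaries (mean, median, P5, P95)
    are computed over the retained subpopulation from ``raw_exposure`` — the
    non-RPF-scaled matrix — when given, else from ``X``.
    """
    if mcr_threshold is not None and mcr_threshold <= 1:
        raise ValueError(f"mcr_threshold must be > 1 or None, got {mcr_threshold}")
    # prune all-zero columns before decomposition
    nonzero = X.columns[(X > 0).any(axis=0)]
    Xp = X[nonzero]
    if mcr_threshold is not None:
        mcr = compute_mcr(Xp)
        keep = mcr > mcr_threshold
        n_keep = int(keep.sum())
        if n_keep == 0:
            raise ValueError(
                f"no individuals with MCR > {mcr_threshold} (0 of {len(Xp)} "
                "rows survive the threshold)"
            )
        Xp = Xp[keep.fillna(False)]
    mixtures = snmu(Xp, k=k, sparsity=sparsity, tol=tol, max_iter=max_iter, seed=seed)
    summary_source = raw_exposure if raw_exposure is not None else X
    summary_source = summary_source.loc[Xp.index]
    for mix in mixtures:
        rows = []
        for comp, wgt in mix.components:
            col = summary_source[comp] if comp in summary_source else pd.Series(dtype=float)
            rows.append({
                "compound": comp,
                "snmu_weight": wgt,
                "mean": col.mean() if len(col) else np.nan,
                "median": col.median() if len(col) else np.nan,
                "p5": col.quantile(0.05) if len(col) else np.nan,
                "p95": col.quantile(0.95) if len(col) else np.nan,
            })
        mix.summaries = pd.DataFrame(rows)
    return mixtures
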