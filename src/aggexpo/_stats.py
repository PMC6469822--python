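"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def _interp_quantile(values: np.ndarray, weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Weighted quantiles by linear interpolation over cumulative-weight
    midpoints; reduces to numpy's ``method='linear'`` for equal weights."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("weights must have positive sum")
    pos = (cw - 0.5 * w) / total
    if pos[-1] > pos[0]:
        pos = (pos - pos[0]) / (pos[-1] - pos[0])
    else:
        pos = np.zeros_like(pos)
    return np.interp(q, pos, v)


def weighted_quantile(values, quantiles, weights=None, zero_mass: float = 0.0):
    """Weighted empirical quantiles with linear interpolation.

    ``zero_mass`` is the probability of an exact zero (the unexposed share of
    the population), handled as an atom: quantile levels at or below
    ``zero_mass`` return 0 exactly; higher levels are mapped into the exposed
    part of the mixture at the rescaled level ``(q - zero_mass) /
    (1 - zero_mass)``.
    """
    values = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(quantiles, dtype=float))
    scalar = np.isscalar(quantiles) or getattr(quantiles, "ndim", 1) == 0
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must be in [0, 1]")
    if not 0.0 <= zero_mass <= 1.0:
        raise ValueError(f"zero_mass must be in [0,1], got {zero_mass}")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if zero_mass >= 1.0:
        out = np.zeros_like(q)
        return float(out[0]) if scalar else out
    if values.size == 0:
        raise ValueError("cannot take quantiles of an empty set")
    if zero_mass > 0:
        q_inner = np.clip((q - zero_mass) / (1.0 - zero_mass), 0.0, 1.0)
        inner = _interp_quantile(values, weights, q_inner)
        out = np.where(q <= zero_mass, 0.0, inner)
    else:
        out = _interp_quantile(values, weights, q)
    return float(out[0]) if scalar else out


def weighted_mean(values, weights=None, zero_mass: float = 0.0) -> float:
    """Weighted mean of a mixture with a point mass of ``zero_mass`` at 0."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    m = float(np.average(values, weights=weights))
    return m * (1.0 - zero_mass)
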