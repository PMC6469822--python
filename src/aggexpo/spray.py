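"""Resident spray-drift exposure surrogate.

Simulates chronic daily unit-dose exposure triples (dermal, oral, inhalation;
mg/day per 1 kg/ha applied) for a resident living at a random distance
downwind of a sprayed field.  Seasonal deposition decays with distance as a
power law, summed over boom passes, scaled by a log-normal wind multiplier,
split across routes by fixed fractions and averaged over the spraying season:

    deposition(d, w) = w * sum_p  c * (d + p * s)**(-e),   p = 0..n_passes-1
    triple = deposition * (f_dermal, f_oral, f_inhalation) / averaging_days

with d ~ Uniform(distance_range) and w log-normal with mean 1 and the
configured coefficient of variation.  All three routes share the same (d, w)
draw, which induces the positive correlation between routes that a shared
physical drift process produces.  Exposure is exactly linear in applied dose,
so unit-dose triples rescale multiplicatively to any recorded dose rate.

This is a deliberately simple parametric family with the scenario geometry of
a boom (arable) or axial-fan (orchard) sprayer; any externally generated
unit-dose table in the same format may be substituted for it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .config import ScenarioSettings

TRIPLE_COLUMNS = ["draw_id", "uncertainty_id", "dermal", "oral", "inhalation"]


def product_dose_rate(concentration_g_per_l: float, product_dose_l_per_ha: float) -> float:
    """Applied dose rate (kg/ha) from product concentration (g/l) and product
    dose (l/ha); e.g. 250 g/l at 4 l/ha gives the unit dose of 1 kg/ha."""
    return concentration_g_per_l * product_dose_l_per_ha / 1000.0


def _wind_multiplier(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal multiplier with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _deposition(settings: ScenarioSettings, d: np.ndarray) -> np.ndarray:
    """Seasonal deposition per unit wind multiplier at distances ``d``."""
    passes = np.arange(settings.n_passes)
    dist = d[:, None] + passes[None, :] * settings.pass_spacing_m
    return (settings.drift_coefficient * dist ** (-settings.drift_exponent)).sum(axis=1)


def _simulate(settings: ScenarioSettings, n: int, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = settings.distance_range_m
    d = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    w = _wind_multiplier(rng, settings.wind_speed_cv, n)
    dep = _deposition(settings, d) * w
    f_dermal, f_inhal, f_oral = settings.route_fractions
    daily = dep / settings.averaging_days
    return pd.DataFrame({
        "draw_id": np.arange(1, n + 1),
        "uncertainty_id": 0,
        "dermal": daily * f_dermal,
        "oral": daily * f_oral,
        "inhalation": daily * f_inhal,
    })


def simulate_unit_dose(settings: ScenarioSettings, n: int, seed: int) -> pd.DataFrame:
    """Simulate ``n`` unit-dose triples (columns dermal, oral, inhalation in
    mg/day per kg/ha) for one scenario."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = substream(seed, "spray_variability")
    return _simulate(settings, n, rng)


def simulate_unit_dose_with_uncertainty(
    settings: ScenarioSettings, n: int, n_uncertainty: int, seed: int
) -> pd.DataFrame:
    """Two-dimensional unit-dose simulation separating uncertainty from
    variability.

    Per uncertainty realisation, the drift coefficient and exponent are
    perturbed by log-normal factors (mean 1, with the settings' uncertainty
    CVs) held fixed within the realisation; ``n`` variability triples are
    then simulated using common random numbers across realisations, so with a
    degenerate uncertainty distribution every realisation reproduces
    :func:`simulate_unit_dose` exactly.  Realisations are labelled by
    ``uncertainty_id`` 1..n_uncertainty.
    """
    if n < 1 or n_uncertainty < 1:
        raise ValueError("n and n_uncertainty must be >= 1")
    u_rng = substream(seed, "spray_uncertainty")
    cv_c = settings.drift_coefficient_uncertainty_cv
    cv_e = settings.drift_exponent_uncertainty_cv
    factors_c = _wind_multiplier(u_rng, cv_c, n_uncertainty)
    factors_e = _wind_multiplier(u_rng, cv_e, n_uncertainty)
    frames = []
    for u in range(n_uncertainty):
        perturbed = ScenarioSettings(
            **{
                **settings.__dict__,
                "drift_coefficient": settings.drift_coefficient * factors_c[u],
                "drift_exponent": settings.drift_exponent * factors_e[u],
            }
        )
        # common random numbers: same variability stream in every realisation
        rng = substream(seed, "spray_variability")
        df = _simulate(perturbed, n, rng)
        df["uncertainty_id"] = u + 1
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def rescale_standard_dose(
    triples: pd.DataFrame, standard_dose: float, target_dose: float
) -> pd.DataFrame:
    """Rescale triples simulated at ``standard_dose`` (kg/ha) to
    ``target_dose``; exposure is linear in dose, so this is multiplication by
    target/standard (e.g. 0.2 -> 1.0 kg/ha multiplies by 5)."""
    if standard_dose <= 0:
        raise ValueError(f"standard_dose must be > 0, got {standard_dose}")
    out = triples.copy()
    factor = target_dose / standard_dose
    for col in ("dermal", "oral", "inhalation"):
        out[col] = out[col] * factor
    return out
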