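"""Weibull survival mathematics for the transition-probability inputs.

The chemotherapy reference arm is described by Weibull curves
``S(t) = exp(-scale * t**shape)`` fitted to digitized Kaplan-Meier data.
The cohort model consumes the *monthly* event probability

    P(t) = 1 - S(t) / S(t-1) = 1 - exp(scale*(t-1)**shape - scale*t**shape),

i.e. the probability of the event during cycle ``t`` given event-free at
``t-1``. TKI arms are derived from the reference arm by multiplying the
monthly odds of *remaining event-free* by the treatment's odds ratio, so an
OR above one lengthens survival.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .parameters import WeibullCurve

__all__ = [
    "weibull_survival",
    "monthly_event_prob",
    "apply_odds_ratio",
    "fit_weibull_to_km",
    "read_km_csv",
    "write_km_csv",
]


def weibull_survival(curve: WeibullCurve, t):
    """Survival fraction S(t) = exp(-scale * t**shape); t in months, >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-curve.scale * t**curve.shape)
    return float(out) if out.ndim == 0 else out


def monthly_event_prob(curve: WeibullCurve, t):
    """Probability of the event during cycle t (integer >= 1) given event-free at t-1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index must be >= 1")
    lam, gam = curve.scale, curve.shape
    out = 1.0 - np.exp(lam * (t - 1.0) ** gam - lam * t**gam)
    return float(out) if out.ndim == 0 else out


def apply_odds_ratio(p_event, or_value):
    """Rescale an event probability by multiplying the odds of remaining event-free.

    With ``q = 1 - p_event`` the adjusted probability is
    ``p' = p / (p + or * q)``; OR > 1 therefore *reduces* the event
    probability (better survival). Absorbing endpoints map to themselves
    (p=0 -> 0, p=1 -> 1). Broadcasts over array arguments.
    """
    p = np.asarray(p_event, dtype=float)
    o = np.asarray(or_value, dtype=float)
    if np.any(o <= 0):
        raise ValueError("odds ratio must be > 0")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("event probability must lie in [0, 1]")
    out = p / (p + o * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def fit_weibull_to_km(points) -> WeibullCurve:
    """Least-squares Weibull fit to Kaplan-Meier points.

    Uses the standard linearization ``ln(-ln s) = ln(scale) + shape*ln(t)``
    and ordinary least squares. ``points`` is a two-column structure
    ``(time_months, survival)``; rows with survival outside the open
    interval (0, 1) carry no information on the log-log scale and are
    dropped with a warning.
    """
    pts = np.asarray(points, dtype=float) if not isinstance(points, pd.DataFrame) \
        else points[["time_months", "survival"]].to_numpy(dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (time, survival)")
    t, s = pts[:, 0], pts[:, 1]
    usable = (s > 0) & (s < 1) & (t > 0)
    if np.any(~usable):
        warnings.warn(
            f"excluding {int(np.sum(~usable))} Kaplan-Meier point(s) with "
            "survival outside (0, 1)",
            stacklevel=2,
        )
    t, s = t[usable], s[usable]
    if t.size < 3:
        raise ValueError("need at least 3 Kaplan-Meier points with 0 < survival < 1")
    shape, logscale = np.polyfit(np.log(t), np.log(-np.log(s)), 1)
    return WeibullCurve(scale=float(np.exp(logscale)), shape=float(shape))


def read_km_csv(path) -> pd.DataFrame:
    """Read Kaplan-Meier points from a two-column CSV (time_months, survival)."""
    df = pd.read_csv(path)
    if not {"time_months", "survival"}.issubset(df.columns):
        raise ValueError("KM CSV must have columns time_months, survival")
    return df[["time_months", "survival"]]


def write_km_csv(points: pd.DataFrame, path) -> None:
    points[["time_months", "survival"]].to_csv(path, index=False)
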