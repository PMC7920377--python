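"""Synthetic individual-patient survival data.

The survival inputs of the cohort model originate, upstream, from
Kaplan-Meier curves that were digitized and re-fitted with Weibull
distributions. This module generates individual-patient data (IPD) with
exactly that statistical structure -- Weibull event times for the reference
arm, odds-ratio-scaled discrete monthly event times for a TKI-like arm,
administrative censoring at a single cutoff -- so the whole input pipeline
(simulate -> Kaplan-Meier -> Weibull fit -> odds-ratio recovery) is testable
end to end without any external data.

IPD is carried as a DataFrame with columns ``id, arm, time_months, event``
(event=True means observed, False means censored at the cutoff) and
round-trips through CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .parameters import WeibullCurve
from .survival import apply_odds_ratio, fit_weibull_to_km, monthly_event_prob

__all__ = [
    "simulate_ipd",
    "simulate_ipd_discrete",
    "km_estimate",
    "life_table_monthly_probs",
    "RecoveryResult",
    "end_to_end_recovery",
]

IPD_COLUMNS = ["id", "arm", "time_months", "event"]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_ipd(
    curve: WeibullCurve, n: int, cutoff: float, seed, arm: str = "control"
) -> pd.DataFrame:
    """Draw n Weibull event times by inverse transform, censored at ``cutoff``.

    S(t) = exp(-scale * t**shape) inverts to t = (-ln U / scale)**(1/shape)
    with U uniform on (0, 1).
    """
    if n < 1:
        raise ValueError("need n >= 1 patients")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    rng = _as_rng(seed)
    u = rng.uniform(size=n)
    times = (-np.log(u) / curve.scale) ** (1.0 / curve.shape)
    event = times <= cutoff
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": arm,
            "time_months": np.where(event, times, cutoff),
            "event": event,
        }
    )


def simulate_ipd_discrete(
    curve: WeibullCurve,
    or_value: float,
    n: int,
    cutoff_months: int,
    seed,
    arm: str = "tki",
) -> pd.DataFrame:
    """Discrete monthly event times with odds-ratio-scaled monthly hazards.

    Each month t carries the reference arm's monthly event probability with
    the odds of remaining event-free multiplied by ``or_value`` -- the same
    per-cycle mechanics the Markov engine uses. Patients event-free after
    ``cutoff_months`` months are censored there.
    """
    if n < 1:
        raise ValueError("need n >= 1 patients")
    if cutoff_months < 1:
        raise ValueError("cutoff_months must be >= 1")
    rng = _as_rng(seed)
    months = np.arange(1, cutoff_months + 1)
    p = apply_odds_ratio(monthly_event_prob(curve, months), or_value)
    surv = np.cumprod(1.0 - p)  # S(t) at t = 1..cutoff
    u = rng.uniform(size=n)
    # event in month t iff S(t) < u <= S(t-1); searchsorted on descending S
    idx = np.searchsorted(-surv, -u, side="left")
    event = idx < cutoff_months
    times = np.where(event, months[np.minimum(idx, cutoff_months - 1)], cutoff_months)
    return pd.DataFrame(
        {"id": np.arange(n), "arm": arm, "time_months": times.astype(float), "event": event}
    )


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate at each distinct event time.

    Returns KM points ``(time_months, survival)`` suitable for
    :func:`nsclc_cea.survival.fit_weibull_to_km`.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    times = records["time_months"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    if not events.any():
        warnings.warn("no events observed; survival estimate is trivially 1", stacklevel=2)
        return pd.DataFrame({"time_months": [float(times.max())], "survival": [1.0]})
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(times[events])
    return pd.DataFrame(
        {
            "time_months": event_times,
            "survival": sf.loc[event_times].to_numpy(dtype=float),
        }
    )


def life_table_monthly_probs(records: pd.DataFrame, n_months: int) -> pd.DataFrame:
    """Actuarial monthly event probabilities: events in (t-1, t] / at risk at t-1."""
    times = records["time_months"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    rows = []
    for t in range(1, n_months + 1):
        at_risk = int(np.sum(times > t - 1))
        d = int(np.sum(events & (times > t - 1) & (times <= t)))
        rows.append(
            {"month": t, "at_risk": at_risk, "events": d,
             "p_event": d / at_risk if at_risk else np.nan}
        )
    return pd.DataFrame(rows).set_index("month")


@dataclass(frozen=True)
class RecoveryResult:
    """Parameters recovered by the simulate -> KM -> fit pipeline."""

    curve: WeibullCurve
    odds_ratio: float


def end_to_end_recovery(
    truth: WeibullCurve,
    or_true: float,
    n: int,
    seed,
    cutoff_months: int = 36,
) -> RecoveryResult:
    """Validation harness for the survival-input construction pipeline.

    Simulates a reference arm from ``truth`` (continuous times) and a
    TKI-like arm by applying ``or_true`` to each monthly event probability;
    Kaplan-Meier-estimates both; fits a Weibull to the reference arm's KM
    points at integer months; and recovers the odds ratio by inverting the
    monthly odds transform on the two arms' life-table event probabilities
    (inverse-variance-weighted on the log-OR scale).
    """
    rng = _as_rng(seed)
    ctrl = simulate_ipd(truth, n, float(cutoff_months), rng, arm="control")
    tki = simulate_ipd_discrete(truth, or_true, n, cutoff_months, rng, arm="tki")
    if not ctrl["event"].any() or not tki["event"].any():
        raise ValueError("degenerate arms: no events observed")

    # Weibull fit on the control KM curve evaluated at integer months
    kmf = KaplanMeierFitter().fit(ctrl["time_months"], ctrl["event"])
    months = np.arange(1, cutoff_months + 1, dtype=float)
    s = kmf.survival_function_at_times(months).to_numpy(dtype=float)
    pts = pd.DataFrame({"time_months": months, "survival": s})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = fit_weibull_to_km(pts)

    lt_c = life_table_monthly_probs(ctrl, cutoff_months)
    lt_t = life_table_monthly_probs(tki, cutoff_months)
    log_or, weight = [], []
    for t in range(1, cutoff_months + 1):
        dc, dt = lt_c.loc[t, "events"], lt_t.loc[t, "events"]
        nc, nt = lt_c.loc[t, "at_risk"], lt_t.loc[t, "at_risk"]
        if min(dc, dt) < 1 or dc >= nc or dt >= nt:
            continue
        pc, pt = dc / nc, dt / nt
        # odds of remaining event-free, TKI over control
        log_or.append(np.log(((1 - pt) / pt) / ((1 - pc) / pc)))
        # inverse of the binomial log-odds variance sum
        var = 1 / dc + 1 / (nc - dc) + 1 / dt + 1 / (nt - dt)
        weight.append(1.0 / var)
    if not log_or:
        raise ValueError("degenerate arms: no month with events in both arms")
    or_hat = float(np.exp(np.average(log_or, weights=weight)))
    return RecoveryResult(curve=fitted, odds_ratio=or_hat)
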