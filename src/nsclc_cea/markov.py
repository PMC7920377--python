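"""Three-state monthly Markov cohort model.

States are progression-free survival (PFS), progressed disease (PD) and
death (absorbing). The whole cohort starts in PFS. Each monthly cycle the
death probability comes from the overall-survival Weibull curve (OR-adjusted
in TKI arms) and applies to PFS and PD occupants alike, so the alive
fraction tracks the fitted OS curve exactly; progression applies to PFS
occupants who survive the cycle, treating the PFS-event and death
probabilities as independent within-cycle risks:

    PFS -> DEATH : p_death(t)
    PFS -> PD    : (1 - p_death(t)) * p_pfs_event(t)
    PD  -> DEATH : p_death(t)

Costs and QALYs are accumulated on beginning-of-cycle state membership
(cycle 0 counted, no half-cycle correction) and discounted at 3% per annum;
PFS/OS months are reported undiscounted. A guided strategy is the
prevalence-times-compliance-weighted mixture of the TKI arm and the
chemotherapy arm, plus a one-time EGFR test cost at entry.

The private :func:`_arm_outcome` engine broadcasts over a leading draw axis,
so the probabilistic sensitivity analysis evaluates all Monte-Carlo draws in
one vectorized pass; :func:`run_cohort` / :func:`accumulate_outcomes` form
the transparent scalar reference path used by ``evaluate_strategy`` and by
the test-suite cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .parameters import ARMS, CHEMO_ARM, SAE_EVENTS, TKIS, ModelParameters
from .survival import apply_odds_ratio, monthly_event_prob

__all__ = [
    "HealthState",
    "STRATEGIES",
    "STRATEGY_ARMS",
    "StrategyOutcome",
    "transition_matrix_at",
    "run_cohort",
    "trace_frame",
    "sae_burden",
    "accumulate_outcomes",
    "evaluate_strategy",
    "evaluate_all_strategies",
    "outcomes_frame",
]


class HealthState(IntEnum):
    PFS = 0
    PD = 1
    DEATH = 2


STRATEGIES = ("empirical", "guided_afatinib", "guided_erlotinib", "guided_gefitinib")

#: TKI arm backing each guided strategy (the empirical strategy is pure chemo)
STRATEGY_ARMS = {
    "guided_afatinib": "afatinib",
    "guided_erlotinib": "erlotinib",
    "guided_gefitinib": "gefitinib",
}


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected discounted cost and QALYs, undiscounted PFS/OS months."""

    cost: float
    qaly: float
    pfs_months: float
    os_months: float


Value = Callable[[str], np.ndarray | float]


def _getter(params: ModelParameters, overrides: Mapping | None) -> Value:
    if not overrides:
        return lambda name: params.value(name)

    def get(name: str):
        v = overrides.get(name)
        return params.value(name) if v is None else v

    return get


# ---------------------------------------------------------------------------
# transition mechanics
# ---------------------------------------------------------------------------

def _arm_probs(params: ModelParameters, arm: str, get: Value):
    """Monthly (p_pfs_event, p_death) for cycles 1..horizon; broadcasts ORs."""
    if arm not in ARMS:
        raise ValueError(f"unknown treatment arm {arm!r}")
    t = np.arange(1, params.horizon_months + 1)
    p_pfs = monthly_event_prob(params.chemo_pfs, t)
    p_death = monthly_event_prob(params.chemo_os, t)
    if arm in TKIS:
        or_pfs = np.asarray(get(f"or_pfs_{arm}"), dtype=float)
        or_os = np.asarray(get(f"or_os_{arm}"), dtype=float)
        p_pfs = apply_odds_ratio(p_pfs, or_pfs[..., None])
        p_death = apply_odds_ratio(p_death, or_os[..., None])
    return np.broadcast_arrays(p_pfs, p_death)


def transition_matrix_at(arm: str, t: int, params: ModelParameters) -> np.ndarray:
    """3x3 one-cycle transition matrix (rows/cols ordered PFS, PD, DEATH)."""
    if not 1 <= t <= params.horizon_months:
        raise ValueError(f"cycle index {t} outside 1..{params.horizon_months}")
    p_pfs, p_death = _arm_probs(params, arm, _getter(params, None))
    P, D = float(np.ravel(p_pfs[..., t - 1])[0]), float(np.ravel(p_death[..., t - 1])[0])
    to_pd = (1.0 - D) * P
    return np.array(
        [
            [1.0 - to_pd - D, to_pd, D],
            [0.0, 1.0 - D, D],
            [0.0, 0.0, 1.0],
        ]
    )


def run_cohort(arm: str, params: ModelParameters) -> np.ndarray:
    """Cohort trace: (horizon+1, 3) state-occupancy fractions, row 0 = (1,0,0)."""
    H = params.horizon_months
    trace = np.zeros((H + 1, 3))
    trace[0, HealthState.PFS] = 1.0
    for t in range(1, H + 1):
        trace[t] = trace[t - 1] @ transition_matrix_at(arm, t, params)
    return trace


def trace_frame(trace: np.ndarray) -> pd.DataFrame:
    """Cycle-indexed occupancy table for CSV export."""
    return pd.DataFrame(trace, columns=["pfs", "pd", "death"]).rename_axis("cycle")


# ---------------------------------------------------------------------------
# rewards
# ---------------------------------------------------------------------------

def _sae_terms(params: ModelParameters, arm: str, get: Value):
    cost = 0.0
    qaly_loss = 0.0
    for e in SAE_EVENTS:
        inc = np.asarray(get(f"sae_incidence_{arm}_{e}"), dtype=float)
        cost = cost + inc * np.asarray(get(f"cost_sae_{e}"), dtype=float)
        qaly_loss = qaly_loss + inc * np.abs(get(f"disutility_{e}"))
    return cost, qaly_loss * params.sae_duration_months / 12.0


def sae_burden(arm: str, params: ModelParameters):
    """One-time expected SAE cost (USD) and QALY decrement at treatment start."""
    cost, qaly_loss = _sae_terms(params, arm, _getter(params, None))
    return float(cost), float(qaly_loss)


def _pfs_month_cost(params: ModelParameters, arm: str, get: Value) -> np.ndarray:
    """Per-cycle cost of PFS-state occupancy, cycles 1..horizon.

    TKI arms pay the TKI monthly cost for every progression-free month
    (treatment until progression). The chemotherapy arm pays the
    cisplatin-pemetrexed monthly cost for the first ``chemo_duration_months``
    (prorated in the partial month) and off-chemotherapy follow-up after.
    """
    H = params.horizon_months
    drug = np.asarray(get(f"cost_month_{arm}"), dtype=float)
    if arm in TKIS:
        return np.broadcast_to(drug[..., None], drug.shape + (H,)).copy()
    frac_on = np.clip(params.chemo_duration_months - np.arange(H), 0.0, 1.0)
    follow = np.asarray(get("cost_month_followup"), dtype=float)
    return drug[..., None] * frac_on + follow[..., None] * (1.0 - frac_on)


def _discount_factors(params: ModelParameters) -> np.ndarray:
    cycles = np.arange(params.horizon_months)
    return (1.0 + params.discount_rate_annual) ** (-cycles / 12.0)


def _arm_outcome(params: ModelParameters, arm: str, get: Value):
    """Vectorized (cost, qaly, pfs_months, os_months) for one treatment arm."""
    H = params.horizon_months
    p_pfs, p_death = _arm_probs(params, arm, get)
    shape = p_pfs.shape[:-1]
    pfs = np.ones(shape)
    pd_ = np.zeros(shape)
    occ_pfs = np.empty(shape + (H,))
    occ_pd = np.empty(shape + (H,))
    for i in range(H):
        occ_pfs[..., i] = pfs
        occ_pd[..., i] = pd_
        D = p_death[..., i]
        to_pd = (1.0 - D) * p_pfs[..., i]
        pfs, pd_ = pfs * (1.0 - to_pd - D), pd_ * (1.0 - D) + pfs * to_pd

    d = _discount_factors(params)
    u_pfs = np.asarray(get("utility_pfs"), dtype=float)[..., None]
    u_pd = np.asarray(get("utility_pd"), dtype=float)[..., None]
    sae_cost, sae_qaly = _sae_terms(params, arm, get)

    pfs_months = occ_pfs.sum(axis=-1)
    os_months = pfs_months + occ_pd.sum(axis=-1)
    qaly = (d * (occ_pfs * u_pfs + occ_pd * u_pd)).sum(axis=-1) / 12.0 - sae_qaly
    cost_pfs = _pfs_month_cost(params, arm, get)
    c_pal = np.asarray(get("cost_month_palliative"), dtype=float)[..., None]
    cost = (d * (occ_pfs * cost_pfs + occ_pd * c_pal)).sum(axis=-1) + sae_cost
    return cost, qaly, pfs_months, os_months


def accumulate_outcomes(
    trace: np.ndarray, arm: str, params: ModelParameters
) -> StrategyOutcome:
    """Scalar reference accumulation of rewards over a cohort trace.

    State membership is counted at the beginning of each of the
    ``horizon_months`` cycles (trace rows 0..H-1); discounting applies
    factor ``(1+r)^(-cycle/12)`` to that cycle's cost and utility.
    """
    H = params.horizon_months
    occ_pfs = trace[:H, HealthState.PFS]
    occ_pd = trace[:H, HealthState.PD]
    d = _discount_factors(params)
    get = _getter(params, None)
    sae_cost, sae_qaly = _sae_terms(params, arm, get)
    pfs_months = float(occ_pfs.sum())
    os_months = float(occ_pfs.sum() + occ_pd.sum())
    qaly = float(
        (d * (occ_pfs * params.utility_pfs + occ_pd * params.utility_pd)).sum() / 12.0
        - sae_qaly
    )
    cost_pfs = np.ravel(_pfs_month_cost(params, arm, get))
    cost = float(
        (d * (occ_pfs * cost_pfs + occ_pd * params.value("cost_month_palliative"))).sum()
        + sae_cost
    )
    return StrategyOutcome(cost=cost, qaly=qaly, pfs_months=pfs_months, os_months=os_months)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def evaluate_strategy(strategy: str, params: ModelParameters) -> StrategyOutcome:
    """Expected outcome of one strategy under the base-case inputs.

    ``empirical`` is the pure chemotherapy arm. A guided strategy mixes the
    TKI arm (weight = prevalence x compliance) with the chemotherapy arm and
    adds the one-time EGFR test cost for all tested patients at entry.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    chemo = accumulate_outcomes(run_cohort(CHEMO_ARM, params), CHEMO_ARM, params)
    if strategy == "empirical":
        return chemo
    arm = STRATEGY_ARMS[strategy]
    tki = accumulate_outcomes(run_cohort(arm, params), arm, params)
    w = params.prevalence_egfr_pos * params.tki_compliance
    return StrategyOutcome(
        cost=w * tki.cost + (1 - w) * chemo.cost + params.value("cost_egfr_test"),
        qaly=w * tki.qaly + (1 - w) * chemo.qaly,
        pfs_months=w * tki.pfs_months + (1 - w) * chemo.pfs_months,
        os_months=w * tki.os_months + (1 - w) * chemo.os_months,
    )


def evaluate_all_strategies(
    params: ModelParameters, overrides: Mapping | None = None
) -> dict[str, StrategyOutcome]:
    """All four strategies on one (possibly vectorized) parameter draw.

    ``overrides`` maps flat parameter names to replacement values; array
    values of common shape ``(n,)`` evaluate n Monte-Carlo draws at once
    (outcome fields are then arrays). All strategies share the same draw.
    """
    get = _getter(params, overrides)
    chemo = _arm_outcome(params, CHEMO_ARM, get)
    prev = np.asarray(get("prevalence_egfr_pos"), dtype=float)
    w = prev * np.asarray(get("tki_compliance"), dtype=float)
    test = np.asarray(get("cost_egfr_test"), dtype=float)
    out: dict[str, StrategyOutcome] = {
        "empirical": StrategyOutcome(*(np.asarray(x) + 0.0 for x in chemo))
    }
    for strategy, arm in STRATEGY_ARMS.items():
        tki = _arm_outcome(params, arm, get)
        cost, qaly, pfs_m, os_m = (
            w * a + (1 - w) * b for a, b in zip(tki, chemo)
        )
        out[strategy] = StrategyOutcome(
            cost=cost + test, qaly=qaly, pfs_months=pfs_m, os_months=os_m
        )
    return out


def outcomes_frame(outcomes: Mapping[str, StrategyOutcome]) -> pd.DataFrame:
    """One summary row per strategy (scalar outcomes only)."""
    return pd.DataFrame(
        {
            "strategy": list(outcomes),
            "cost": [float(o.cost) for o in outcomes.values()],
            "qaly": [float(o.qaly) for o in outcomes.values()],
            "pfs_months": [float(o.pfs_months) for o in outcomes.values()],
            "os_months": [float(o.os_months) for o in outcomes.values()],
        }
    ).set_index("strategy")
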