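"""Incremental cost-effectiveness analysis.

Strict dominance elimination (a strategy gaining fewer QALYs at higher cost
than another is dominated), ICERs versus a common comparator and versus the
next-less-costly strategy on the efficiency frontier, and the
willingness-to-pay decision rule. The operational rule is net monetary
benefit (NMB = WTP * QALY - cost) maximization, which is equivalent to the
two-clause "cost-saving or ICER below WTP" ladder walked along the frontier;
the equivalence is exercised by the test suite. Extended dominance is
reported as a diagnostic only and never used for elimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .markov import StrategyOutcome

__all__ = [
    "GDP_PER_CAPITA",
    "WTP_1X_GDP",
    "WTP_3X_GDP",
    "IcerRow",
    "DominanceResult",
    "net_monetary_benefit",
    "dominance_frontier",
    "icer_table",
    "frontier_icer_table",
    "icer_frame",
    "preferred_strategy",
    "extended_dominance",
]

#: Hong Kong GDP per capita (USD, 2019); 3x GDP is the base-case WTP threshold.
GDP_PER_CAPITA = 47812.0
WTP_1X_GDP = GDP_PER_CAPITA
WTP_3X_GDP = 3 * GDP_PER_CAPITA  # 143,436 USD/QALY


@dataclass(frozen=True)
class IcerRow:
    strategy: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None  # USD per QALY; None when flagged
    flag: str = ""  # "", "dominating", "dominated", "undefined"


@dataclass(frozen=True)
class DominanceResult:
    """Non-dominated strategies sorted by ascending cost, plus eliminations."""

    frontier: list[str]
    dominated_by: dict[str, str]  # eliminated strategy -> its dominator


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    return wtp * outcome.qaly - outcome.cost


def _strictly_dominates(a: StrategyOutcome, b: StrategyOutcome) -> bool:
    """True if b gains fewer QALYs at higher cost than a."""
    return a.qaly > b.qaly and a.cost < b.cost


def dominance_frontier(outcomes: Mapping[str, StrategyOutcome]) -> DominanceResult:
    """Eliminate strictly dominated strategies; frontier sorted by cost."""
    if not outcomes:
        raise ValueError("need at least one strategy")
    dominated_by: dict[str, str] = {}
    for name, o in outcomes.items():
        dominators = [
            other for other, oo in outcomes.items()
            if other != name and _strictly_dominates(oo, o)
        ]
        if dominators:
            # label with the highest-QALY dominator (ties by lower cost, name)
            dominated_by[name] = min(
                dominators,
                key=lambda s: (-outcomes[s].qaly, outcomes[s].cost, s),
            )
    frontier = sorted(
        (n for n in outcomes if n not in dominated_by),
        key=lambda s: (outcomes[s].cost, outcomes[s].qaly, s),
    )
    return DominanceResult(frontier=frontier, dominated_by=dominated_by)


def _row(strategy: str, comparator: str, s: StrategyOutcome, c: StrategyOutcome) -> IcerRow:
    dc = float(s.cost - c.cost)
    dq = float(s.qaly - c.qaly)
    if dq == 0.0 and dc == 0.0:
        return IcerRow(strategy, comparator, dc, dq, None, "undefined")
    if dq > 0 and dc <= 0:
        return IcerRow(strategy, comparator, dc, dq, None, "dominating")
    if dq <= 0 and dc >= 0:
        return IcerRow(strategy, comparator, dc, dq, None, "dominated")
    if dq == 0.0:
        return IcerRow(strategy, comparator, dc, dq, None, "undefined")
    # remaining cases: both negative (ICER of forgoing) or both positive
    return IcerRow(strategy, comparator, dc, dq, dc / dq, "")


def icer_table(
    outcomes: Mapping[str, StrategyOutcome], comparator: str
) -> list[IcerRow]:
    """One row per non-comparator strategy versus the common comparator."""
    if comparator not in outcomes:
        raise ValueError(f"comparator {comparator!r} not among outcomes")
    c = outcomes[comparator]
    return [
        _row(name, comparator, o, c) for name, o in outcomes.items() if name != comparator
    ]


def frontier_icer_table(outcomes: Mapping[str, StrategyOutcome]) -> list[IcerRow]:
    """Sequential ICERs along the frontier (each versus the next less costly)."""
    front = dominance_frontier(outcomes).frontier
    rows = []
    for prev, nxt in zip(front[:-1], front[1:]):
        rows.append(_row(nxt, prev, outcomes[nxt], outcomes[prev]))
    return rows


def icer_frame(rows: list[IcerRow]) -> pd.DataFrame:
    """ICER rows as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "comparator": [r.comparator for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "delta_qaly": [r.delta_qaly for r in rows],
            "icer": [r.icer if r.icer is not None else math.nan for r in rows],
            "flag": [r.flag for r in rows],
        }
    )


def preferred_strategy(outcomes: Mapping[str, StrategyOutcome], wtp: float) -> str:
    """Strategy with maximal net monetary benefit at the given WTP.

    Ties are broken by lower cost, then lexical name.
    """
    if not outcomes:
        raise ValueError("need at least one strategy")
    if wtp < 0:
        raise ValueError("WTP must be >= 0")
    return min(
        outcomes,
        key=lambda s: (-net_monetary_benefit(outcomes[s], wtp), outcomes[s].cost, s),
    )


def extended_dominance(outcomes: Mapping[str, StrategyOutcome]) -> list[str]:
    """Diagnostic: frontier strategies that are extendedly dominated.

    A frontier strategy is extendedly dominated when the sequential ICER of
    reaching it exceeds the sequential ICER of the next step up, i.e. a
    mixture of its neighbours yields more QALYs at the same cost. Reported
    only; elimination uses strict dominance alone.
    """
    front = dominance_frontier(outcomes).frontier
    flagged: list[str] = []
    changed = True
    while changed and len(front) >= 3:
        changed = False
        for i in range(1, len(front) - 1):
            lo, mid, hi = front[i - 1], front[i], front[i + 1]
            icer_lo = _row(mid, lo, outcomes[mid], outcomes[lo]).icer
            icer_hi = _row(hi, mid, outcomes[hi], outcomes[mid]).icer
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                flagged.append(mid)
                front = front[:i] + front[i + 1:]
                changed = True
                break
    return flagged
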