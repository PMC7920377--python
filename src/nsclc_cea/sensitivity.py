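"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-evaluates all strategies with a single input moved to
the extremes of its published range. The threshold scan bisects one
parameter against an arbitrary decision criterion (e.g. "frontier ICER of
guided afatinib below the WTP threshold"). The probabilistic sensitivity
analysis (PSA) redraws every non-fixed input from its distribution family
-- Beta for probabilities and prevalences (moment-matched to the base value
and a range treated as a 95% interval), Triangular for odds ratios,
utilities and costs (mode at the base value, the printed range as hard
bounds) -- and recomputes all four strategies on the *same* draw, so
incremental scatter and acceptability curves are built from paired samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cea import WTP_3X_GDP, preferred_strategy
from .markov import STRATEGIES, StrategyOutcome, evaluate_all_strategies
from .parameters import ModelParameters, ParamSpec

__all__ = [
    "DEFAULT_SEED",
    "PsaResults",
    "OneWayResult",
    "sample_parameter",
    "one_way_analysis",
    "one_way_table",
    "threshold_scan",
    "run_psa",
    "pairwise_acceptance",
    "acceptability_curves",
]

logger = logging.getLogger(__name__)

#: default PSA seed (publication date of the underlying analysis)
DEFAULT_SEED = 20210301


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _beta_shapes(spec: ParamSpec) -> tuple[float, float]:
    """Moment-matched Beta shapes: mean = base, sd = (high-low)/(2*1.96).

    If the implied variance is infeasible for a Beta law the (low, high)
    anchors are re-interpreted as the 1st/99th percentiles and the shapes
    solved numerically (logged when it happens).
    """
    mean = spec.base
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    if sd <= 0:
        raise ValueError(f"{spec.name}: beta sampling needs high > low")
    if sd * sd < mean * (1.0 - mean):
        nu = mean * (1.0 - mean) / (sd * sd) - 1.0
        return mean * nu, (1.0 - mean) * nu
    logger.info(
        "%s: beta moment matching infeasible (sd=%.4g); fitting (low, high) "
        "as 1st/99th percentiles", spec.name, sd,
    )

    def resid(x):
        a, b = np.exp(x)  # keep shapes positive
        return [
            stats.beta.ppf(0.01, a, b) - spec.low,
            stats.beta.ppf(0.99, a, b) - spec.high,
        ]

    sol = optimize.root(resid, x0=[0.0, 0.0])
    if not sol.success:
        raise ValueError(f"{spec.name}: could not fit beta to percentile anchors")
    a, b = np.exp(sol.x)
    return float(a), float(b)


def sample_parameter(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from the parameter's PSA distribution.

    ``fixed`` returns the base value; ``triangular`` draws from
    Triangular(low, mode=base, high); ``beta`` moment-matches mean/sd as
    described above. Degenerate anchors (low == high, or a Beta mean of
    exactly 0 or 1, which arises for adverse events printed as 0%) collapse
    to the point mass at the base value.
    """
    degenerate = spec.low == spec.high or (
        spec.distribution == "beta" and spec.base in (0.0, 1.0)
    )
    if spec.distribution == "fixed" or degenerate:
        return spec.base if size is None else np.full(size, spec.base)
    if spec.distribution == "triangular":
        return rng.triangular(spec.low, spec.base, spec.high, size)
    if spec.distribution == "beta":
        a, b = _beta_shapes(spec)
        return rng.beta(a, b, size)
    raise ValueError(f"{spec.name}: unknown distribution {spec.distribution!r}")


# ---------------------------------------------------------------------------
# one-way analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    low: float
    high: float
    outcomes_low: dict[str, StrategyOutcome]
    outcomes_high: dict[str, StrategyOutcome]
    preferred_low: str
    preferred_high: str

    @property
    def preferred_changes(self) -> bool:
        return self.preferred_low != self.preferred_high


def _scalar_outcomes(
    params: ModelParameters, overrides: Mapping[str, float] | None = None
) -> dict[str, StrategyOutcome]:
    out = evaluate_all_strategies(params, overrides)
    return {
        s: StrategyOutcome(*(float(getattr(o, f)) for f in
                             ("cost", "qaly", "pfs_months", "os_months")))
        for s, o in out.items()
    }


def one_way_analysis(
    params: ModelParameters, parameter: str, wtp: float = WTP_3X_GDP
) -> OneWayResult:
    """Re-evaluate all strategies with one input at each end of its range."""
    spec = params.spec(parameter)
    out_lo = _scalar_outcomes(params, {parameter: spec.low})
    out_hi = _scalar_outcomes(params, {parameter: spec.high})
    return OneWayResult(
        parameter=parameter,
        low=spec.low,
        high=spec.high,
        outcomes_low=out_lo,
        outcomes_high=out_hi,
        preferred_low=preferred_strategy(out_lo, wtp),
        preferred_high=preferred_strategy(out_hi, wtp),
    )


def one_way_table(params: ModelParameters, wtp: float = WTP_3X_GDP) -> pd.DataFrame:
    """One-way results over every input with a non-degenerate range."""
    rows = []
    for name, spec in sorted(params.specs.items()):
        if spec.low == spec.high:
            continue
        r = one_way_analysis(params, name, wtp)
        base_pref = preferred_strategy(_scalar_outcomes(params), wtp)
        rows.append(
            {
                "parameter": name,
                "low": spec.low,
                "base": spec.base,
                "high": spec.high,
                "preferred_low": r.preferred_low,
                "preferred_high": r.preferred_high,
                "threshold_crossed": r.preferred_low != base_pref
                or r.preferred_high != base_pref,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def threshold_scan(
    params: ModelParameters,
    parameter: str,
    lo: float,
    hi: float,
    criterion: Callable[[dict[str, StrategyOutcome]], bool],
    tol: float = 1.0,
    pre_scan_points: int = 50,
) -> float | None:
    """Bisect one parameter for the value at which ``criterion`` flips.

    ``criterion`` receives the strategy-outcome map at a candidate value.
    Returns None when the criterion is identical at both ends; raises if a
    pre-scan on ``pre_scan_points`` grid points shows the indicator is not
    monotone over [lo, hi] (a manual grid search is then required).
    """
    if not lo < hi:
        raise ValueError("need lo < hi")

    def crit_at(x: float) -> bool:
        return bool(criterion(_scalar_outcomes(params, {parameter: x})))

    grid = np.linspace(lo, hi, pre_scan_points)
    flags = [crit_at(x) for x in grid]
    flips = sum(a != b for a, b in zip(flags[:-1], flags[1:]))
    if flips == 0:
        return None
    if flips > 1:
        raise ValueError(
            f"criterion is not monotone in {parameter!r} over [{lo}, {hi}]; "
            "use a manual grid"
        )
    a, b = lo, hi
    fa = flags[0]
    while b - a > tol:
        mid = 0.5 * (a + b)
        if crit_at(mid) == fa:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaResults:
    """Per-draw discounted cost and QALYs for each strategy.

    ``draws`` holds the sampled parameter values (one column per non-fixed
    input); ``outcomes`` has columns ``cost_<strategy>``/``qaly_<strategy>``.
    """

    n_sims: int
    seed: int
    draws: pd.DataFrame
    outcomes: pd.DataFrame

    def cost(self, strategy: str) -> np.ndarray:
        return self.outcomes[f"cost_{strategy}"].to_numpy()

    def qaly(self, strategy: str) -> np.ndarray:
        return self.outcomes[f"qaly_{strategy}"].to_numpy()

    def incremental(self, strategy: str, comparator: str) -> pd.DataFrame:
        """Paired (delta_cost, delta_qaly) scatter data."""
        return pd.DataFrame(
            {
                "delta_cost": self.cost(strategy) - self.cost(comparator),
                "delta_qaly": self.qaly(strategy) - self.qaly(comparator),
            }
        )

    def save(self, directory: str | Path, stem: str = "psa") -> None:
        """Write per-draw results plus a JSON run manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.outcomes.to_csv(directory / f"{stem}_outcomes.csv", index=False)
        self.draws.to_csv(directory / f"{stem}_draws.csv", index=False)
        manifest = {
            "n_sims": self.n_sims,
            "seed": self.seed,
            "strategies": list(STRATEGIES),
            "parameters": sorted(self.draws.columns),
        }
        (directory / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_psa(
    params: ModelParameters, n_sims: int = 10_000, seed: int = DEFAULT_SEED
) -> PsaResults:
    """Monte-Carlo PSA: common random parameter draws across all strategies.

    Every input whose distribution is not ``fixed`` (and not degenerate) is
    sampled once per draw; the Weibull survival parameters, compliance and
    the model settings stay at base case. Reproducible for a given seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    overrides: dict[str, np.ndarray] = {}
    for name in sorted(params.specs):  # fixed order => reproducibility
        spec = params.specs[name]
        if spec.distribution == "fixed":
            continue
        overrides[name] = np.asarray(sample_parameter(spec, rng, size=n_sims))
    out = evaluate_all_strategies(params, overrides)
    cols = {}
    for s in STRATEGIES:
        cols[f"cost_{s}"] = np.broadcast_to(out[s].cost, (n_sims,))
        cols[f"qaly_{s}"] = np.broadcast_to(out[s].qaly, (n_sims,))
    return PsaResults(
        n_sims=n_sims,
        seed=seed,
        draws=pd.DataFrame(overrides),
        outcomes=pd.DataFrame(cols),
    )


def pairwise_acceptance(
    psa: PsaResults, strategy: str, comparator: str, wtp: float = WTP_3X_GDP
) -> float:
    """Fraction of draws in which ``strategy`` is cost-effective vs ``comparator``.

    A draw counts when the QALY gain is positive and the strategy is either
    cost-saving or has ICER below the WTP threshold.
    """
    dq = psa.qaly(strategy) - psa.qaly(comparator)
    dc = psa.cost(strategy) - psa.cost(comparator)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (dq > 0) & ((dc < 0) | (dc / dq < wtp))
    return float(np.mean(ok))


def acceptability_curves(psa: PsaResults, wtp_grid) -> pd.DataFrame:
    """Probability each strategy has maximal NMB, per WTP point.

    Returns a frame indexed by ``wtp`` with one probability column per
    strategy; rows sum to one. Ties (measure zero in practice) are awarded
    to the cheaper strategy, then lexical order, matching
    :func:`nsclc_cea.cea.preferred_strategy`.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be nonempty")
    costs = np.stack([psa.cost(s) for s in STRATEGIES])  # (4, n)
    qalys = np.stack([psa.qaly(s) for s in STRATEGIES])
    lexical = np.argsort(np.argsort(STRATEGIES)).astype(float)  # tie rank by name
    rows = []
    for w in wtp_grid:
        nmb = w * qalys - costs
        is_best = nmb == nmb.max(axis=0)
        # among draws' NMB maximizers pick the cheapest, then lexically first
        cand_cost = np.where(is_best, costs, np.inf)
        winner = np.argmin(cand_cost + 1e-9 * lexical[:, None], axis=0)
        probs = [float(np.mean(winner == i)) for i in range(len(STRATEGIES))]
        rows.append({"wtp": w, **dict(zip(STRATEGIES, probs))})
    return pd.DataFrame(rows).set_index("wtp")
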