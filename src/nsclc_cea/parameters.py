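"""Typed registry of the model inputs.

Every uncertain scalar input (prevalence, odds ratios, utilities,
disutilities, adverse-event incidences, unit costs, compliance) is stored as
a :class:`ParamSpec` carrying its base-case value, the range used by
deterministic sensitivity analysis and the distribution family used by the
probabilistic sensitivity analysis. Structural constants (the Weibull
survival parameters of the chemotherapy reference arm, the discount rate,
the horizon and the chemotherapy/SAE durations) live directly on
:class:`ModelParameters`.

Parameters are addressed by flat names, e.g. ``utility_pfs``,
``or_pfs_erlotinib``, ``sae_incidence_cisplatin_pemetrexed_neutropenic_fever``
or ``cost_month_afatinib``; ``ModelParameters.specs`` maps every such name to
its :class:`ParamSpec`, and :meth:`ModelParameters.with_base` returns a copy
with one value replaced (the workhorse of one-way sensitivity analysis).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SAE_EVENTS",
    "TKIS",
    "ARMS",
    "CHEMO_ARM",
    "ParamSpec",
    "WeibullCurve",
    "TreatmentProfile",
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "default_parameters",
]

SAE_EVENTS = ("nausea_vomiting", "diarrhea", "rash", "anemia", "neutropenic_fever")
TKIS = ("afatinib", "erlotinib", "gefitinib")
CHEMO_ARM = "cisplatin_pemetrexed"
ARMS = TKIS + (CHEMO_ARM,)

_DISTRIBUTIONS = ("beta", "triangular", "fixed")

#: flat names of parameters constrained to [0, 1]
_PROBABILITY_PREFIXES = ("prevalence_", "sae_incidence_", "tki_compliance", "utility_")


class ParameterError(ValueError):
    """Raised when a configuration file is missing keys or violates invariants."""


@dataclass(frozen=True)
class ParamSpec:
    """One model input: base-case value, sensitivity range, PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"

    def violations(self) -> list[str]:
        out = []
        if self.distribution not in _DISTRIBUTIONS:
            out.append(f"{self.name}: unknown distribution {self.distribution!r}")
        if not (self.low <= self.base <= self.high):
            out.append(
                f"{self.name}: range not ordered (low={self.low}, base={self.base}, "
                f"high={self.high})"
            )
        if self.name.startswith(_PROBABILITY_PREFIXES):
            if not (0.0 <= self.low and self.high <= 1.0):
                out.append(f"{self.name}: probability outside [0, 1]")
        if self.name.startswith("disutility_") and self.base > 0:
            out.append(f"{self.name}: disutility must be <= 0")
        if self.name.startswith("cost_") and self.low < 0:
            out.append(f"{self.name}: costs must be >= 0")
        if self.name.startswith("or_") and self.low <= 0:
            out.append(f"{self.name}: odds ratios must be > 0")
        if self.distribution == "beta" and not (0.0 <= self.base <= 1.0):
            out.append(f"{self.name}: beta distribution requires base in [0, 1]")
        return out


@dataclass(frozen=True)
class WeibullCurve:
    """Parametric survival curve S(t) = exp(-scale * t**shape), t in months."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.shape > 0 and math.isfinite(self.scale)):
            raise ParameterError(
                f"Weibull parameters must be strictly positive, got "
                f"scale={self.scale}, shape={self.shape}"
            )


@dataclass(frozen=True)
class TreatmentProfile:
    """View of one treatment arm's inputs (ORs absent for chemotherapy)."""

    name: str
    or_pfs: ParamSpec | None
    or_os: ParamSpec | None
    monthly_cost: ParamSpec
    sae_incidences: Mapping[str, ParamSpec]


@dataclass(frozen=True)
class ModelParameters:
    """Complete input set for the Markov model.

    ``specs`` maps flat parameter names to their :class:`ParamSpec`;
    everything else is a structural constant.
    """

    chemo_pfs: WeibullCurve
    chemo_os: WeibullCurve
    specs: Mapping[str, ParamSpec] = field(default_factory=dict)
    discount_rate_annual: float = 0.03
    horizon_months: int = 120
    chemo_duration_months: float = 4.2
    sae_duration_months: float = 1.0

    # -- access helpers -------------------------------------------------
    def spec(self, name: str) -> ParamSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self.spec(name).base

    def with_base(self, name: str, value: float) -> "ModelParameters":
        """Copy with one parameter's base-case value replaced."""
        old = self.spec(name)
        specs = dict(self.specs)
        specs[name] = dataclasses.replace(old, base=value)
        return dataclasses.replace(self, specs=specs)

    def treatment(self, arm: str) -> TreatmentProfile:
        if arm not in ARMS:
            raise ParameterError(f"unknown treatment arm {arm!r}")
        is_tki = arm in TKIS
        return TreatmentProfile(
            name=arm,
            or_pfs=self.spec(f"or_pfs_{arm}") if is_tki else None,
            or_os=self.spec(f"or_os_{arm}") if is_tki else None,
            monthly_cost=self.spec(f"cost_month_{arm}"),
            sae_incidences={
                e: self.spec(f"sae_incidence_{arm}_{e}") for e in SAE_EVENTS
            },
        )

    @property
    def prevalence_egfr_pos(self) -> float:
        return self.value("prevalence_egfr_pos")

    @property
    def utility_pfs(self) -> float:
        return self.value("utility_pfs")

    @property
    def utility_pd(self) -> float:
        return self.value("utility_pd")

    @property
    def tki_compliance(self) -> float:
        return self.value("tki_compliance")


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def _spec(name: str, node, path: str) -> ParamSpec:
    if not isinstance(node, Mapping):
        raise ParameterError(f"{path}: expected a mapping with base/low/high")
    try:
        base = float(node["base"])
    except KeyError:
        raise ParameterError(f"{path}: missing key 'base'") from None
    low = float(node.get("low", base))
    high = float(node.get("high", base))
    dist = str(node.get("distribution", "fixed"))
    return ParamSpec(name=name, base=base, low=low, high=high, distribution=dist)


def _require(cfg: Mapping, key: str, path: str):
    try:
        return cfg[key]
    except (KeyError, TypeError):
        raise ParameterError(f"missing configuration key {path + key!r}") from None


def _parse(cfg: Mapping) -> ModelParameters:
    specs: dict[str, ParamSpec] = {}

    specs["prevalence_egfr_pos"] = _spec(
        "prevalence_egfr_pos", _require(cfg, "prevalence_egfr_pos", ""), "prevalence_egfr_pos"
    )
    specs["tki_compliance"] = _spec(
        "tki_compliance", _require(cfg, "tki_compliance", ""), "tki_compliance"
    )

    wb = _require(cfg, "weibull", "")
    curves = {}
    for key in ("chemo_pfs", "chemo_os"):
        node = _require(wb, key, "weibull.")
        curves[key] = WeibullCurve(
            scale=float(_require(node, "scale", f"weibull.{key}.")),
            shape=float(_require(node, "shape", f"weibull.{key}.")),
        )

    treatments = _require(cfg, "treatments", "")
    for arm in ARMS:
        node = _require(treatments, arm, "treatments.")
        if arm in TKIS:
            for kind in ("or_pfs", "or_os"):
                specs[f"{kind}_{arm}"] = _spec(
                    f"{kind}_{arm}", _require(node, kind, f"treatments.{arm}."),
                    f"treatments.{arm}.{kind}",
                )
        specs[f"cost_month_{arm}"] = _spec(
            f"cost_month_{arm}", _require(node, "monthly_cost", f"treatments.{arm}."),
            f"treatments.{arm}.monthly_cost",
        )
        inc = _require(node, "sae_incidence", f"treatments.{arm}.")
        for e in SAE_EVENTS:
            specs[f"sae_incidence_{arm}_{e}"] = _spec(
                f"sae_incidence_{arm}_{e}", _require(inc, e, f"treatments.{arm}.sae_incidence."),
                f"treatments.{arm}.sae_incidence.{e}",
            )

    util = _require(cfg, "utilities", "")
    specs["utility_pfs"] = _spec("utility_pfs", _require(util, "pfs", "utilities."), "utilities.pfs")
    specs["utility_pd"] = _spec("utility_pd", _require(util, "pd", "utilities."), "utilities.pd")

    dis = _require(cfg, "disutilities", "")
    for e in SAE_EVENTS:
        specs[f"disutility_{e}"] = _spec(
            f"disutility_{e}", _require(dis, e, "disutilities."), f"disutilities.{e}"
        )

    costs = _require(cfg, "costs", "")
    specs["cost_egfr_test"] = _spec(
        "cost_egfr_test", _require(costs, "egfr_test", "costs."), "costs.egfr_test"
    )
    specs["cost_month_followup"] = _spec(
        "cost_month_followup", _require(costs, "followup_month", "costs."), "costs.followup_month"
    )
    specs["cost_month_palliative"] = _spec(
        "cost_month_palliative", _require(costs, "palliative_month", "costs."),
        "costs.palliative_month",
    )
    sae_costs = _require(costs, "sae_episode", "costs.")
    for e in SAE_EVENTS:
        specs[f"cost_sae_{e}"] = _spec(
            f"cost_sae_{e}", _require(sae_costs, e, "costs.sae_episode."), f"costs.sae_episode.{e}"
        )

    settings = cfg.get("settings", {}) or {}
    params = ModelParameters(
        chemo_pfs=curves["chemo_pfs"],
        chemo_os=curves["chemo_os"],
        specs=specs,
        discount_rate_annual=float(settings.get("discount_rate_annual", 0.03)),
        horizon_months=int(settings.get("horizon_months", 120)),
        chemo_duration_months=float(settings.get("chemo_duration_months", 4.2)),
        sae_duration_months=float(settings.get("sae_duration_months", 1.0)),
    )

    violations = validate_parameters(params)
    if violations:
        raise ParameterError("invalid parameters:\n" + "\n".join(violations))
    return params


def load_parameters(config_path: str | Path | None = None) -> ModelParameters:
    """Load model parameters from a YAML/JSON config (packaged default if None)."""
    if config_path is None:
        text = (resources.files("nsclc_cea") / "data" / "table1.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ParameterError("configuration file does not contain a mapping")
    return _parse(cfg)


def default_parameters() -> ModelParameters:
    """The packaged base-case input set."""
    return load_parameters(None)


def _spec_node(s: ParamSpec) -> dict:
    return {"base": s.base, "low": s.low, "high": s.high, "distribution": s.distribution}


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize to YAML; ``load_parameters`` of the result round-trips."""
    p = params
    cfg: dict = {
        "prevalence_egfr_pos": _spec_node(p.spec("prevalence_egfr_pos")),
        "tki_compliance": _spec_node(p.spec("tki_compliance")),
        "weibull": {
            "chemo_pfs": {"scale": p.chemo_pfs.scale, "shape": p.chemo_pfs.shape},
            "chemo_os": {"scale": p.chemo_os.scale, "shape": p.chemo_os.shape},
        },
        "treatments": {},
        "utilities": {
            "pfs": _spec_node(p.spec("utility_pfs")),
            "pd": _spec_node(p.spec("utility_pd")),
        },
        "disutilities": {e: _spec_node(p.spec(f"disutility_{e}")) for e in SAE_EVENTS},
        "costs": {
            "egfr_test": _spec_node(p.spec("cost_egfr_test")),
            "followup_month": _spec_node(p.spec("cost_month_followup")),
            "palliative_month": _spec_node(p.spec("cost_month_palliative")),
            "sae_episode": {e: _spec_node(p.spec(f"cost_sae_{e}")) for e in SAE_EVENTS},
        },
        "settings": {
            "discount_rate_annual": p.discount_rate_annual,
            "horizon_months": p.horizon_months,
            "chemo_duration_months": p.chemo_duration_months,
            "sae_duration_months": p.sae_duration_months,
        },
    }
    for arm in ARMS:
        node: dict = {}
        if arm in TKIS:
            node["or_pfs"] = _spec_node(p.spec(f"or_pfs_{arm}"))
            node["or_os"] = _spec_node(p.spec(f"or_os_{arm}"))
        node["monthly_cost"] = _spec_node(p.spec(f"cost_month_{arm}"))
        node["sae_incidence"] = {
            e: _spec_node(p.spec(f"sae_incidence_{arm}_{e}")) for e in SAE_EVENTS
        }
        cfg["treatments"][arm] = node
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def validate_parameters(params: ModelParameters) -> list[str]:
    """Return a list of invariant violations (empty iff the inputs are valid)."""
    out: list[str] = []
    for name, spec in params.specs.items():
        if spec.name != name:
            out.append(f"{name}: registry key does not match spec name {spec.name!r}")
        out.extend(spec.violations())
    if params.horizon_months < 1:
        out.append("horizon_months: must be >= 1")
    if params.discount_rate_annual < 0:
        out.append("discount_rate_annual: must be >= 0")
    if params.chemo_duration_months < 0:
        out.append("chemo_duration_months: must be >= 0")
    if params.sae_duration_months < 0:
        out.append("sae_duration_months: must be >= 0")
    return out
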