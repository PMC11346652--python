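"""Verification-trial metrics: yield deviation, response yardstick, value-cost
ratio, and nutrient-use efficiencies.

Two unit conventions in this metric suite deserve attention, because reported
trial tables are only internally consistent under them:

* the response-yardstick denominator sums fertilizer nutrients on the OXIDE
  basis for P and K (N + P2O5 + K2O) and EXCLUDES manure nutrients;
* partial factor productivity divides total biomass (fresh cob + dry stover)
  expressed in quintals (t x 10) by the dose as kg N / P2O5 / K2O.

Recovery efficiency, by contrast, uses elemental doses.  Each function
exposes the literal textbook alternative behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_data import NutrientTriple
from .units import ELEMENTAL, K_TO_K2O, OXIDE, P_TO_P2O5

__all__ = [
    "TreatmentOutcome",
    "CostModel",
    "percent_deviation",
    "response_yardstick",
    "value_cost_ratio",
    "recovery_efficiency",
    "partial_factor_productivity",
    "reciprocal_internal_ue",
    "evaluate_trial",
]

_NUTRIENTS = ("n", "p", "k")


@dataclass(frozen=True)
class TreatmentOutcome:
    """One verification-trial treatment: doses, yields, uptakes, target."""

    treatment: str
    doses: NutrientTriple  # elemental kg/ha
    fym_rate: float
    cob_yield: float  # t/ha fresh
    stover_yield: float  # t/ha dry
    uptake: NutrientTriple  # total kg/ha
    cob_uptake: NutrientTriple | None = None
    target_t: float | None = None

    def __post_init__(self) -> None:
        if self.cob_yield < 0 or self.stover_yield < 0:
            raise ValueError(f"{self.treatment}: yields must be >= 0")
        if self.fym_rate < 0:
            raise ValueError(f"{self.treatment}: fym_rate must be >= 0")


@dataclass(frozen=True)
class CostModel:
    """Input prices for the value-cost ratio.

    Nutrient prices are per kg applied (on whatever basis the doses you pass
    are on); FYM per tonne; produce price per tonne of fresh cob.
    """

    price_n: float
    price_p: float
    price_k: float
    price_fym_per_t: float
    cob_price_per_t: float

    def __post_init__(self) -> None:
        for f in ("price_n", "price_p", "price_k", "price_fym_per_t", "cob_price_per_t"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def input_cost(self, doses: NutrientTriple, fym_rate: float) -> float:
        return (
            self.price_n * doses.n
            + self.price_p * doses.p
            + self.price_k * doses.k
            + self.price_fym_per_t * fym_rate
        )


def percent_deviation(actual_yield: float, target: float) -> float:
    """100 x (actual - target) / target."""
    if target <= 0:
        raise ValueError(f"target must be > 0, got {target}")
    return 100.0 * (actual_yield - target) / target


def _total_nutrients(doses: NutrientTriple, basis: str) -> float:
    if basis == OXIDE:
        d = doses.to_basis(OXIDE)
    else:
        d = doses.to_basis(ELEMENTAL)
    return d.n + d.p + d.k


def response_yardstick(
    out: TreatmentOutcome,
    control: TreatmentOutcome,
    *,
    denominator_basis: str = OXIDE,
    include_fym_nutrients: bool = False,
    fym_nutrients_kg: NutrientTriple | None = None,
) -> float:
    """Yield response (kg/ha over control) per kg of fertilizer nutrients.

    Default denominator: N + P2O5 + K2O of the fertilizer doses only.
    """
    if any(control.doses[x] != 0 for x in _NUTRIENTS):
        raise ValueError("control treatment must have all-zero fertilizer doses")
    denom = _total_nutrients(out.doses, denominator_basis)
    if include_fym_nutrients:
        if fym_nutrients_kg is None:
            raise ValueError("fym_nutrients_kg required when include_fym_nutrients")
        denom += _total_nutrients(fym_nutrients_kg, denominator_basis)
    if denom <= 0:
        raise ValueError(f"{out.treatment}: zero total nutrients applied")
    return (out.cob_yield - control.cob_yield) * 1000.0 / denom


def value_cost_ratio(
    out: TreatmentOutcome, control: TreatmentOutcome, costs: CostModel
) -> float:
    """Monetary value of the yield response per unit input cost."""
    cost = costs.input_cost(out.doses, out.fym_rate)
    if cost <= 0:
        raise ValueError(f"{out.treatment}: zero input cost")
    return (out.cob_yield - control.cob_yield) * costs.cob_price_per_t / cost


def recovery_efficiency(
    uptake_treated: float, uptake_control: float, dose: float
) -> float:
    """(uptake_treated - uptake_control) / dose, dose in elemental kg/ha."""
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    return (uptake_treated - uptake_control) / dose


def partial_factor_productivity(
    cob_yield: float,
    stover_yield: float,
    dose: float,
    nutrient: str,
    *,
    convention: str = "biomass_quintal_oxide",
) -> float:
    """Produce per kg of nutrient applied.

    ``biomass_quintal_oxide`` (default): (cob + stover) x 10 quintals per kg
    of N / P2O5 / K2O — the convention that published trial tables follow.
    ``cob_elemental``: fresh cob t/ha per elemental kg, the literal formula.
    """
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    nutrient = nutrient.lower()
    if convention == "biomass_quintal_oxide":
        factor = {"n": 1.0, "p": P_TO_P2O5, "k": K_TO_K2O}[nutrient]
        return (cob_yield + stover_yield) * 10.0 / (dose * factor)
    if convention == "cob_elemental":
        return cob_yield / dose
    raise ValueError(f"unknown convention {convention!r}")


def reciprocal_internal_ue(cob_uptake: float, cob_yield: float) -> float:
    """Cob nutrient uptake (kg/ha) per tonne of fresh cob yield."""
    if cob_yield <= 0:
        raise ValueError(f"cob_yield must be > 0, got {cob_yield}")
    return cob_uptake / cob_yield


def evaluate_trial(
    outcomes: Sequence[TreatmentOutcome],
    control_id: str,
    costs: CostModel | None = None,
    *,
    reference_target: float | None = None,
) -> pd.DataFrame:
    """Assemble the full metric table, one row per treatment.

    Percent deviation uses each treatment's own ``target_t``, falling back to
    ``reference_target`` for non-targeted comparator treatments when given.
    Metrics whose inputs are absent (prices, cob-only uptakes, zero doses)
    are reported as NaN, never as zero.
    """
    by_id = {o.treatment: o for o in outcomes}
    if control_id not in by_id:
        raise ValueError(f"control treatment {control_id!r} not present")
    control = by_id[control_id]
    rows = []
    for o in outcomes:
        row: dict = {
            "treatment": o.treatment,
            "cob_yield": o.cob_yield,
            "stover_yield": o.stover_yield,
        }
        target = o.target_t if o.target_t is not None else reference_target
        row["pct_deviation"] = (
            percent_deviation(o.cob_yield, target) if target else np.nan
        )
        is_control = o.treatment == control_id
        has_dose = any(o.doses[x] > 0 for x in _NUTRIENTS)
        row["rys"] = (
            response_yardstick(o, control) if has_dose and not is_control else np.nan
        )
        row["vcr"] = (
            value_cost_ratio(o, control, costs)
            if costs is not None and not is_control and (has_dose or o.fym_rate > 0)
            else np.nan
        )
        for x in _NUTRIENTS:
            dose = o.doses[x]
            row[f"re_{x}"] = (
                recovery_efficiency(o.uptake[x], control.uptake[x], dose)
                if dose > 0 and not is_control
                else np.nan
            )
            row[f"pfp_{x}"] = (
                partial_factor_productivity(o.cob_yield, o.stover_yield, dose, x)
                if dose > 0 and not is_control
                else np.nan
            )
            row[f"riue_{x}"] = (
                reciprocal_internal_ue(o.cob_uptake[x], o.cob_yield)
                if o.cob_uptake is not None and o.cob_yield > 0
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("treatment")
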