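"""Fertilizer prescription equations and dose computation.

From the calibrated basic parameters the targeted-yield approach writes, per
nutrient, a linear dose equation

    F_x = (NR_x / CF_x) * 100 * T  -  (CS_x / CF_x) * STV_x  [- c_om * OM]

with T the yield target (t/ha), STV_x the pre-sowing soil test value (kg/ha)
and OM the manure rate (t/ha).  Two conventions that published equation sets
are ambiguous about are made explicit here:

* ``slope_oxide_conversion`` — whether the slope term is divided by 2.29 (P)
  and 1.205 (K).  Published STCR equations for this system reconcile with
  their own parameter tables only under that division (the STV coefficients
  reconcile without it), so it is the default, and each equation records the
  convention used in its ``notes``.
* ``om_convention`` — the coefficient on OM: the published equations use the
  COM% value verbatim per tonne of manure ("printed", default); the general
  formula would use COM/CF ("formula"); inverting the mass-basis uptake
  model exactly requires 1000*COM/CF ("self_consistent").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calibration import MODE_NPK_FYM, BasicParameters
from .trial_data import NutrientTriple, SoilTest
from .units import ELEMENTAL, K_TO_K2O, P_TO_P2O5, check_basis

__all__ = [
    "NutrientEquation",
    "PrescriptionEquation",
    "DoseRecommendation",
    "derive_equation",
    "prescribe",
    "ready_reckoner",
    "write_equations",
    "read_equations",
]

_NUTRIENTS = ("n", "p", "k")
_OM_CONVENTIONS = ("printed", "formula", "self_consistent")


@dataclass(frozen=True)
class NutrientEquation:
    """One linear dose equation F = slope_t*T - coeff_stv*STV - coeff_om*OM."""

    slope_t: float
    coeff_stv: float
    coeff_om: float = 0.0

    def dose(self, target_t: float, stv: float, fym_rate: float = 0.0) -> float:
        return self.slope_t * target_t - self.coeff_stv * stv - self.coeff_om * fym_rate


@dataclass(frozen=True)
class PrescriptionEquation:
    """The three per-nutrient dose equations for one mode."""

    mode: str
    n: NutrientEquation
    p: NutrientEquation
    k: NutrientEquation
    output_basis: str = ELEMENTAL
    stv_basis: str = ELEMENTAL
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "output_basis", check_basis(self.output_basis))
        object.__setattr__(self, "stv_basis", check_basis(self.stv_basis))
        for x in _NUTRIENTS:
            eq = self[x]
            if eq.slope_t <= 0:
                raise ValueError(f"slope_t for {x} must be > 0, got {eq.slope_t}")
            if eq.coeff_om < 0:
                raise ValueError(f"coeff_om for {x} must be >= 0, got {eq.coeff_om}")

    def __getitem__(self, nutrient: str) -> NutrientEquation:
        return {"n": self.n, "p": self.p, "k": self.k}[nutrient.lower()]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "mode": self.mode,
                "nutrient": x.upper(),
                "slope_t": self[x].slope_t,
                "coeff_stv": self[x].coeff_stv,
                "coeff_om": self[x].coeff_om,
                "output_basis": self.output_basis,
                "stv_basis": self.stv_basis,
            }
            for x in _NUTRIENTS
        ]
        return pd.DataFrame(rows)

    def summary(self, decimals: int = 3) -> str:
        """Human-readable equations, coefficients rounded for presentation."""
        lines = [f"Prescription equations ({self.mode}), doses kg/ha {self.output_basis}:"]
        for x in _NUTRIENTS:
            eq = self[x]
            s = f"  F{x.upper()} = {eq.slope_t:.{decimals}f} T - {eq.coeff_stv:.{decimals}f} S{x.upper()}"
            if self.mode == MODE_NPK_FYM:
                s += f" - {eq.coeff_om:.{decimals}f} OM"
            lines.append(s)
        lines.extend(f"  note: {n}" for n in self.notes)
        return "\n".join(lines)


@dataclass(frozen=True)
class DoseRecommendation:
    """A computed dose, both raw (possibly negative) and clamped at zero."""

    target_t: float
    soil_test: SoilTest
    fym_rate: float
    raw_dose: NutrientTriple
    dose: NutrientTriple
    clamped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x in _NUTRIENTS:
            expected = max(self.raw_dose[x], 0.0)
            if abs(self.dose[x] - expected) > 1e-9:
                raise ValueError("dose must equal raw_dose clamped at zero")


def derive_equation(
    bp: BasicParameters,
    *,
    output_basis: str = ELEMENTAL,
    slope_oxide_conversion: bool = True,
    om_convention: str = "printed",
) -> PrescriptionEquation:
    """Derive the prescription equations from calibrated basic parameters.

    slope_t = (NR/CF)*100, divided by 2.29 / 1.205 for P / K when
    ``slope_oxide_conversion`` is on; coeff_stv = CS/CF; coeff_om per
    ``om_convention`` (see module docstring).  Coefficients are carried at
    full precision; rounding is presentation only.
    """
    if om_convention not in _OM_CONVENTIONS:
        raise ValueError(f"unknown om_convention {om_convention!r}")
    output_basis = check_basis(output_basis)
    notes = []
    eqs = {}
    for x in _NUTRIENTS:
        par = bp[x]
        if par.cf_pct <= 0:
            raise ValueError(f"CF_{x} must be > 0 to derive an equation")
        slope = par.nr / par.cf_pct * 100.0
        if slope_oxide_conversion and x in ("p", "k"):
            slope /= P_TO_P2O5 if x == "p" else K_TO_K2O
        coeff_stv = par.cs_pct / par.cf_pct
        coeff_om = 0.0
        if bp.mode == MODE_NPK_FYM:
            if par.com_pct is None:
                raise ValueError(f"COM_{x} missing; cannot derive integrated equation")
            if om_convention == "printed":
                coeff_om = par.com_pct
            elif om_convention == "formula":
                coeff_om = par.com_pct / par.cf_pct
            else:  # self_consistent: inverts the mass-basis manure uptake credit
                coeff_om = 1000.0 * par.com_pct / par.cf_pct
        if not 0 < coeff_stv <= 1:
            notes.append(f"coeff_stv_{x} = {coeff_stv:.3f} outside the expected (0, 1]")
        eqs[x] = NutrientEquation(slope_t=slope, coeff_stv=coeff_stv, coeff_om=coeff_om)
    if slope_oxide_conversion:
        notes.append(
            "P/K slope terms divided by 2.29/1.205 (oxide->elemental); "
            "STV coefficients left unconverted"
        )
    notes.append(f"om_convention={om_convention}")
    return PrescriptionEquation(
        mode=bp.mode,
        n=eqs["n"],
        p=eqs["p"],
        k=eqs["k"],
        output_basis=output_basis,
        stv_basis=ELEMENTAL,
        notes=tuple(notes),
    )


def prescribe(
    eq: PrescriptionEquation,
    target_t: float,
    soil_test: SoilTest,
    fym_rate: float = 0.0,
    *,
    convert_soil_test: bool = False,
) -> DoseRecommendation:
    """Compute the fertilizer dose for a yield target.

    The soil test must be on the equation's stv basis; pass
    ``convert_soil_test=True`` to convert it explicitly.  Negative raw doses
    (target met by soil supply alone) are clamped to zero and flagged.
    """
    if target_t <= 0:
        raise ValueError(f"target_t must be > 0, got {target_t}")
    if fym_rate < 0:
        raise ValueError(f"fym_rate must be >= 0, got {fym_rate}")
    if soil_test.basis != eq.stv_basis:
        if not convert_soil_test:
            raise ValueError(
                f"soil test basis {soil_test.basis!r} != equation stv basis "
                f"{eq.stv_basis!r}; pass convert_soil_test=True to convert"
            )
        soil_test = soil_test.to_basis(eq.stv_basis)
    raw_vals = {x: eq[x].dose(target_t, soil_test[x], fym_rate) for x in _NUTRIENTS}
    raw = NutrientTriple(**raw_vals, basis=eq.output_basis, raw=True)
    dose = NutrientTriple(
        **{x: max(v, 0.0) for x, v in raw_vals.items()}, basis=eq.output_basis
    )
    return DoseRecommendation(
        target_t=target_t,
        soil_test=soil_test,
        fym_rate=fym_rate,
        raw_dose=raw,
        dose=dose,
        clamped={x: raw_vals[x] < 0 for x in _NUTRIENTS},
    )


def ready_reckoner(
    eq: PrescriptionEquation,
    targets: Sequence[float],
    stv_grid: Iterable[SoilTest],
    fym_rate: float = 0.0,
) -> pd.DataFrame:
    """Cartesian dose table over yield targets and soil-test levels."""
    targets = list(targets)
    stv_grid = list(stv_grid)
    if not targets or not stv_grid:
        raise ValueError("targets and stv_grid must be non-empty")
    rows = []
    for t, stv in itertools.product(targets, stv_grid):
        rec = prescribe(eq, t, stv, fym_rate)
        rows.append(
            {
                "target_t": t,
                "soil_n": stv.sn,
                "soil_p": stv.sp,
                "soil_k": stv.sk,
                "fym_rate": fym_rate,
                "dose_n": rec.dose.n,
                "dose_p": rec.dose.p,
                "dose_k": rec.dose.k,
            }
        )
    return pd.DataFrame(rows)


def write_equations(eq: PrescriptionEquation, path: str | Path) -> Path:
    path = Path(path)
    eq.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def read_equations(path: str | Path) -> PrescriptionEquation:
    df = pd.read_csv(path)
    required = {"mode", "nutrient", "slope_t", "coeff_stv", "coeff_om"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    by_nutrient = {str(r.nutrient).lower(): r for r in df.itertuples()}
    eqs = {
        x: NutrientEquation(
            slope_t=float(by_nutrient[x].slope_t),
            coeff_stv=float(by_nutrient[x].coeff_stv),
            coeff_om=float(by_nutrient[x].coeff_om),
        )
        for x in _NUTRIENTS
    }
    first = df.iloc[0]
    return PrescriptionEquation(
        mode=str(first["mode"]),
        n=eqs["n"],
        p=eqs["p"],
        k=eqs["k"],
        output_basis=str(first.get("output_basis", ELEMENTAL)),
        stv_basis=str(first.get("stv_basis", ELEMENTAL)),
    )
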