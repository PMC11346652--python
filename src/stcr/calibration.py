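"""Calibration of the four STCR basic parameters from a plot table.

The inductive targeted-yield approach summarises a multi-strip calibration
trial by four quantities per nutrient:

* NR   — nutrient requirement, kg of uptake per tonne of economic produce;
* CS%  — percent of control-plot uptake attributable to soil available supply;
* CF%  — percent of the applied fertilizer dose recovered in crop uptake,
         after crediting the soil (and, in the integrated mode, the manure);
* COM% — percent of applied organic-manure MASS recovered in uptake.

Each estimator averages a per-plot ratio over a configurable selection of
plots; CF for potassium routinely exceeds 100% (priming of native K), which
is preserved, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import (
    ROLE_CONTROL,
    ROLE_FYM_ONLY,
    ROLE_NPK_ONLY,
    ROLE_NPK_PLUS_FYM,
    PlotRecord,
    PlotTable,
)

__all__ = [
    "NutrientParams",
    "BasicParameters",
    "SelectionPolicy",
    "StripSummary",
    "nutrient_requirement",
    "soil_contribution",
    "fertilizer_contribution",
    "manure_contribution",
    "calibrate",
    "strip_summary",
    "yield_dose_uptake_correlation",
    "MODE_NPK_ALONE",
    "MODE_NPK_FYM",
]

MODE_NPK_ALONE = "npk_alone"
MODE_NPK_FYM = "npk_fym"
_NUTRIENTS = ("n", "p", "k")

Aggregator = Callable[[Sequence[float]], float]


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values))


@dataclass(frozen=True)
class NutrientParams:
    """Calibrated parameters for one nutrient."""

    nr: float  # kg per t of fresh cob
    cs_pct: float
    cf_pct: float
    com_pct: float | None = None


@dataclass(frozen=True)
class BasicParameters:
    """The full calibrated parameter set for one prescription mode."""

    mode: str
    n: NutrientParams
    p: NutrientParams
    k: NutrientParams
    n_plots_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in (MODE_NPK_ALONE, MODE_NPK_FYM):
            raise ValueError(f"unknown mode {self.mode!r}")
        for x in _NUTRIENTS:
            par = self[x]
            if par.nr <= 0:
                raise ValueError(f"NR_{x} must be > 0, got {par.nr}")
            if par.cs_pct < 0:
                raise ValueError(f"CS_{x} must be >= 0, got {par.cs_pct}")
            if self.mode == MODE_NPK_FYM and par.com_pct is None:
                raise ValueError(f"COM_{x} required in mode {self.mode}")

    def __getitem__(self, nutrient: str) -> NutrientParams:
        return {"n": self.n, "p": self.p, "k": self.k}[nutrient.lower()]

    def to_dataframe(self) -> pd.DataFrame:
        """Parameter grid: rows NR/CS/CF/COM, one column per nutrient."""
        rows = {
            "NR_kg_per_t": [self[x].nr for x in _NUTRIENTS],
            "CS_pct": [self[x].cs_pct for x in _NUTRIENTS],
            "CF_pct": [self[x].cf_pct for x in _NUTRIENTS],
        }
        if self.mode == MODE_NPK_FYM:
            rows["COM_pct"] = [self[x].com_pct for x in _NUTRIENTS]
        return pd.DataFrame(rows, index=["N", "P", "K"]).T

    @classmethod
    def from_values(
        cls,
        mode: str,
        nr: dict,
        cs_pct: dict,
        cf_pct: dict,
        com_pct: dict | None = None,
        n_plots_used: dict | None = None,
    ) -> "BasicParameters":
        params = {}
        for x in _NUTRIENTS:
            params[x] = NutrientParams(
                nr=nr[x],
                cs_pct=cs_pct[x],
                cf_pct=cf_pct[x],
                com_pct=None if com_pct is None else com_pct[x],
            )
        return cls(mode=mode, n=params["n"], p=params["p"], k=params["k"],
                   n_plots_used=n_plots_used or {})


@dataclass(frozen=True)
class SelectionPolicy:
    """Which plot roles feed each estimator.

    The conventional choice (default) pools controls across strips for CS,
    uses fertilizer-only plots for CF in the NPK-alone mode, manure-only
    plots for COM, and fertilizer+manure plots (after soil and manure
    credits) for CF in the integrated mode.  NR averages over every fertilised
    plot of the mode.
    """

    nr_roles: dict = field(
        default_factory=lambda: {
            MODE_NPK_ALONE: (ROLE_NPK_ONLY,),
            MODE_NPK_FYM: (ROLE_NPK_ONLY, ROLE_NPK_PLUS_FYM),
        }
    )
    cf_roles: dict = field(
        default_factory=lambda: {
            MODE_NPK_ALONE: (ROLE_NPK_ONLY,),
            MODE_NPK_FYM: (ROLE_NPK_PLUS_FYM,),
        }
    )
    cs_per_strip_first: bool = False
    truncate_negative: bool = False


def _check_uptake(plots: Iterable[PlotRecord]) -> list[PlotRecord]:
    plots = list(plots)
    if not plots:
        raise ValueError("empty plot selection")
    for r in plots:
        if r.uptake is None:
            raise ValueError(f"plot {r.plot_id} has no uptake data")
    return plots


def _aggregate(values: list[float], aggregator: Aggregator, truncate: bool) -> float:
    if truncate:
        values = [max(v, 0.0) for v in values]
    return aggregator(values)


def nutrient_requirement(
    plots: Iterable[PlotRecord], *, aggregator: Aggregator = _mean
) -> dict:
    """NR (kg/t) per nutrient: per-plot uptake / cob yield, aggregated."""
    plots = _check_uptake(plots)
    out = {}
    for x in _NUTRIENTS:
        ratios = []
        for r in plots:
            if r.cob_yield <= 0:
                raise ValueError(f"plot {r.plot_id}: cob_yield must be > 0 for NR")
            ratios.append(r.uptake[x] / r.cob_yield)
        out[x] = aggregator(ratios)
    return out


def soil_contribution(
    control_plots: Iterable[PlotRecord], *, aggregator: Aggregator = _mean
) -> dict:
    """CS% per nutrient from control plots: 100 x uptake / soil test value."""
    plots = _check_uptake(control_plots)
    out = {}
    for x in _NUTRIENTS:
        ratios = []
        for r in plots:
            if r.role != ROLE_CONTROL:
                raise ValueError(f"plot {r.plot_id} has role {r.role!r}, expected control")
            stv = r.soil_test[x]
            if stv <= 0:
                raise ValueError(f"plot {r.plot_id}: zero soil test value for {x}")
            ratios.append(100.0 * r.uptake[x] / stv)
        out[x] = aggregator(ratios)
    return out


def fertilizer_contribution(
    treated_plots: Iterable[PlotRecord],
    cs_pct: dict,
    *,
    com_pct: dict | None = None,
    aggregator: Aggregator = _mean,
    truncate_negative: bool = False,
) -> dict:
    """CF% per nutrient from fertilised plots.

    Per plot: 100 x (uptake - soil credit [- manure credit]) / dose.  The
    manure credit com_pct x fym_rate x 1000 / 100 applies in the integrated
    mode (``com_pct`` given); values above 100% are preserved.
    """
    plots = _check_uptake(treated_plots)
    out = {}
    for x in _NUTRIENTS:
        ratios = []
        for r in plots:
            dose = r.fert_dose[x]
            if dose <= 0:
                raise ValueError(
                    f"plot {r.plot_id}: zero {x} dose; cannot estimate CF_{x}"
                )
            net = r.uptake[x] - r.soil_test[x] * cs_pct[x] / 100.0
            if com_pct is not None:
                net -= com_pct[x] * r.fym_rate * 1000.0 / 100.0
            ratios.append(100.0 * net / dose)
        out[x] = _aggregate(ratios, aggregator, truncate_negative)
    return out


def manure_contribution(
    fym_plots: Iterable[PlotRecord],
    cs_pct: dict,
    *,
    aggregator: Aggregator = _mean,
    truncate_negative: bool = False,
) -> dict:
    """COM% per nutrient from manure-only plots.

    Per plot: 100 x (uptake - soil credit) / manure mass in kg/ha.  The
    denominator is the MASS of manure applied, so COM values are small
    (order 0.1-1%).
    """
    plots = _check_uptake(fym_plots)
    out = {}
    for x in _NUTRIENTS:
        ratios = []
        for r in plots:
            if r.role != ROLE_FYM_ONLY:
                raise ValueError(f"plot {r.plot_id} has role {r.role!r}, expected fym_only")
            if r.fym_rate <= 0:
                raise ValueError(f"plot {r.plot_id}: zero FYM rate")
            net = r.uptake[x] - r.soil_test[x] * cs_pct[x] / 100.0
            ratios.append(100.0 * net / (r.fym_rate * 1000.0))
        out[x] = _aggregate(ratios, aggregator, truncate_negative)
    return out


def calibrate(
    table: PlotTable,
    mode: str = MODE_NPK_ALONE,
    *,
    policy: SelectionPolicy | None = None,
    aggregator: Aggregator = _mean,
) -> BasicParameters:
    """Estimate the complete basic-parameter set for one prescription mode."""
    if mode not in (MODE_NPK_ALONE, MODE_NPK_FYM):
        raise ValueError(f"unknown mode {mode!r}")
    policy = policy or SelectionPolicy()

    controls = table.select(role=ROLE_CONTROL)
    if not controls:
        raise ValueError("no control plots in table")
    if policy.cs_per_strip_first:
        strips = sorted({r.strip for r in controls})
        per_strip = [
            soil_contribution(
                [r for r in controls if r.strip == s], aggregator=aggregator
            )
            for s in strips
        ]
        cs = {x: float(np.mean([d[x] for d in per_strip])) for x in _NUTRIENTS}
    else:
        cs = soil_contribution(controls, aggregator=aggregator)

    nr_plots = [r for r in table if r.role in policy.nr_roles[mode]]
    if not nr_plots:
        raise ValueError(f"no plots with roles {policy.nr_roles[mode]} for NR")
    nr = nutrient_requirement(nr_plots, aggregator=aggregator)

    com = None
    if mode == MODE_NPK_FYM:
        fym_plots = table.select(role=ROLE_FYM_ONLY)
        if not fym_plots:
            raise ValueError("no fym_only plots; cannot estimate COM")
        com = manure_contribution(
            fym_plots, cs, aggregator=aggregator,
            truncate_negative=policy.truncate_negative,
        )

    cf_plots = [r for r in table if r.role in policy.cf_roles[mode]]
    if not cf_plots:
        raise ValueError(f"no plots with roles {policy.cf_roles[mode]} for CF")
    cf = fertilizer_contribution(
        cf_plots, cs, com_pct=com, aggregator=aggregator,
        truncate_negative=policy.truncate_negative,
    )

    counts = {
        "cs": len(controls),
        "nr": len(nr_plots),
        "cf": len(cf_plots),
    }
    if mode == MODE_NPK_FYM:
        counts["com"] = len(table.select(role=ROLE_FYM_ONLY))
    return BasicParameters.from_values(
        mode=mode, nr=nr, cs_pct=cs, cf_pct=cf, com_pct=com, n_plots_used=counts
    )


# ---------------------------------------------------------------------------
# Descriptive summaries and correlations

@dataclass(frozen=True)
class StripSummary:
    strip: str
    variable: str
    n: int
    mean: float
    sd: float
    cv_pct: float | None
    iqr: float
    skewness: float
    min: float
    max: float


_VARIABLE_GETTERS: dict[str, Callable[[PlotRecord], float]] = {
    "soil_n": lambda r: r.soil_test.sn,
    "soil_p": lambda r: r.soil_test.sp,
    "soil_k": lambda r: r.soil_test.sk,
    "cob_yield": lambda r: r.cob_yield,
    "stover_yield": lambda r: r.stover_yield,
    "uptake_n": lambda r: r.uptake.n,
    "uptake_p": lambda r: r.uptake.p,
    "uptake_k": lambda r: r.uptake.k,
}


def strip_summary(table: PlotTable, variable: str) -> list[StripSummary]:
    """Per-strip descriptive statistics of one plot variable.

    sd is the n-1 sample standard deviation; IQR uses linear-interpolation
    quantiles; skewness is the adjusted Fisher-Pearson sample coefficient.
    CV% is undefined (None) when the mean is zero.
    """
    if variable not in _VARIABLE_GETTERS:
        raise KeyError(
            f"unknown variable {variable!r}; choose from {sorted(_VARIABLE_GETTERS)}"
        )
    getter = _VARIABLE_GETTERS[variable]
    out = []
    for strip in sorted({r.strip for r in table}):
        vals = np.array([getter(r) for r in table.select(strip=strip)], dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty strip group {strip!r}")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        # guard effectively-constant data, where the third moment is round-off
        degenerate = sd <= 1e-12 * abs(mean)
        skew = float(stats.skew(vals, bias=False)) if vals.size > 2 and not degenerate else 0.0
        out.append(
            StripSummary(
                strip=strip,
                variable=variable,
                n=int(vals.size),
                mean=mean,
                sd=sd,
                cv_pct=100.0 * sd / mean if mean != 0 else None,
                iqr=float(q3 - q1),
                skewness=skew,
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return out


def yield_dose_uptake_correlation(table: PlotTable) -> pd.DataFrame:
    """OLS r2 (plus slope/intercept) of cob yield against uptakes and doses.

    One row per regressor (uptake_n/p/k, dose_n/p/k).  A constant regressor
    leaves r2 undefined and is reported as NaN.
    """
    df = table.to_dataframe()
    rows = []
    for col in ("uptake_n", "uptake_p", "uptake_k", "dose_n", "dose_p", "dose_k"):
        sub = df[["cob_yield", col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >=3 plots with cob_yield and {col}, got {len(sub)}")
        x, y = sub[col].to_numpy(), sub["cob_yield"].to_numpy()
        if np.ptp(x) == 0:
            rows.append({"regressor": col, "r2": np.nan, "slope": np.nan,
                         "intercept": np.nan, "n": len(sub)})
            continue
        res = stats.linregress(x, y)
        rows.append(
            {
                "regressor": col,
                "r2": res.rvalue**2,
                "slope": res.slope,
                "intercept": res.intercept,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("regressor")
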