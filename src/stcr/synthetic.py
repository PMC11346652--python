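"""Seeded generators for STCR calibration and verification trials.

The generative model inverts the calibration arithmetic: each plot's nutrient
uptake is the sum of a soil term (cs x STV), a fertilizer term (cf x dose)
and a manure term (com x manure mass), and fresh cob yield is N uptake
divided by the nitrogen requirement NR_N (nitrogen is the yield-defining
nutrient; it shows the strongest yield-uptake correlation in this system).
Multiplicative lognormal noise, mean 1, enters in two places: on measured
uptakes (tissue-analysis / plot variation) and on yield given uptake.

Because P and K uptakes generated from their own contribution terms are not
proportional to an N-driven yield, the per-plot ratio uptake/yield does not
equal NR_P or NR_K plot-by-plot.  The ``per_nutrient_consistency`` option
rescales P/K uptakes to NR_x x yield and back-solves each plot's soil-test
P/K so the contribution decomposition still holds exactly; when the truth
parameters leave no headroom for a non-negative soil test (large mass-basis
manure credits do this), the option raises rather than emitting an
inconsistent table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .prescription import PrescriptionEquation, prescribe
from .trial_data import NutrientTriple, PlotRecord, PlotTable, SoilTest
from .evaluation import TreatmentOutcome
from .units import ELEMENTAL, K_TO_K2O, P_TO_P2O5

__all__ = [
    "TruthParameters",
    "DesignSpec",
    "default_design",
    "default_truth",
    "simulate_gradient",
    "simulate_main_experiment",
    "simulate_verification",
    "VerificationTreatment",
]

_NUTRIENTS = ("n", "p", "k")


@dataclass(frozen=True)
class TruthParameters:
    """Generative ground truth for a synthetic STCR trial.

    nr in kg/t; cs_frac and cf_frac are fractions (Table-style CS%, CF%
    divided by 100); com_pct is on the manure-mass percent scale.  Noise CVs
    are percents.  ``strip_stv_means`` holds one elemental-basis SoilTest per
    fertility strip, ordered low to high N.
    """

    nr: dict
    cs_frac: dict
    cf_frac: dict
    com_pct: dict
    strip_stv_means: tuple
    uptake_noise_cv: float = 5.0
    yield_noise_cv: float = 5.0
    stv_spread_cv: float = 10.0
    stover_ratio: float = 1.5
    cob_uptake_frac: float = 0.25
    noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        for x in _NUTRIENTS:
            if self.nr[x] <= 0:
                raise ValueError(f"nr[{x!r}] must be > 0")
            if self.cs_frac[x] < 0 or self.cf_frac[x] < 0 or self.com_pct[x] < 0:
                raise ValueError("contribution parameters must be >= 0")
        for f in ("uptake_noise_cv", "yield_noise_cv", "stv_spread_cv"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the calibration experiment.

    strips x FYM blocks x NPK subplots; the subplot dose list (elemental
    kg/ha) must contain exactly one all-zero triple — the control of each
    block.
    """

    n_strips: int = 3
    fym_levels: tuple = (0.0, 10.0, 20.0)
    npk_subplot_doses: tuple = ()

    def __post_init__(self) -> None:
        zero = [d for d in self.npk_subplot_doses if d.n == 0 and d.p == 0 and d.k == 0]
        if len(zero) != 1:
            raise ValueError("design must contain exactly one all-zero dose (the control)")

    @property
    def n_plots(self) -> int:
        return self.n_strips * len(self.fym_levels) * len(self.npk_subplot_doses)


def default_design() -> DesignSpec:
    """The 3-strip x 3-FYM-block x 8-subplot (72 plot) calibration layout.

    Dose grids: N 0/75/150/225, P2O5 0/37.5/75/112.5, K2O 0/18.75/37.5/56.25
    kg/ha (stored elemental), seven NPK combinations plus the absolute
    control in every manure block.
    """
    def triple(n: float, p2o5: float, k2o: float) -> NutrientTriple:
        return NutrientTriple(n=n, p=p2o5 / P_TO_P2O5, k=k2o / K_TO_K2O, basis=ELEMENTAL)

    doses = (
        triple(0, 0, 0),
        triple(75, 37.5, 18.75),
        triple(75, 75, 37.5),
        triple(150, 37.5, 18.75),
        triple(150, 75, 37.5),
        triple(150, 112.5, 56.25),
        triple(225, 75, 37.5),
        triple(225, 112.5, 56.25),
    )
    return DesignSpec(n_strips=3, fym_levels=(0.0, 10.0, 20.0), npk_subplot_doses=doses)


def default_truth(mode: str = "npk_alone", **overrides) -> TruthParameters:
    """Truth parameters anchored to the bundled reference sweet-corn system.

    NR/CS/CF/COM come from :func:`stcr.datasets.reference_basic_parameters`
    (converted to fractions) and strip soil-test means from the reference
    post-gradient strips, so simulated tables resemble the real trial.
    """
    from .datasets import REFERENCE_PARAMS, reference_strip_means

    if mode not in REFERENCE_PARAMS:
        raise ValueError(f"unknown mode {mode!r}")
    ref = REFERENCE_PARAMS[mode]
    com = ref["com"] or {x: 0.0 for x in _NUTRIENTS}
    kwargs = dict(
        nr=dict(ref["nr"]),
        cs_frac={x: ref["cs"][x] / 100.0 for x in _NUTRIENTS},
        cf_frac={x: ref["cf"][x] / 100.0 for x in _NUTRIENTS},
        com_pct=dict(com),
        strip_stv_means=reference_strip_means(),
    )
    kwargs.update(overrides)
    return TruthParameters(**kwargs)


def _noise(rng: np.random.Generator, cv_pct: float, size: int, model: str) -> np.ndarray:
    """Mean-1 multiplicative noise factors."""
    if cv_pct == 0:
        return np.ones(size)
    cv = cv_pct / 100.0
    if model == "lognormal":
        sigma = math.sqrt(math.log1p(cv * cv))
        return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)
    return np.clip(rng.normal(loc=1.0, scale=cv, size=size), 0.0, None)


def simulate_gradient(
    truth: TruthParameters, design: DesignSpec, seed: int
) -> pd.DataFrame:
    """Per-plot soil test values for the fertility-gradient layout.

    STV = strip mean x multiplicative spread noise; strips are ordered low to
    high available N, reproducing the deliberate monotone gradient.  Same
    seed, same table.
    """
    if len(truth.strip_stv_means) < design.n_strips:
        raise ValueError("need one strip STV mean per strip")
    rng = np.random.default_rng(seed)
    n_per_strip = len(design.fym_levels) * len(design.npk_subplot_doses)
    rows = []
    for s in range(design.n_strips):
        mean = truth.strip_stv_means[s]
        factors = {
            x: _noise(rng, truth.stv_spread_cv, n_per_strip, truth.noise_model)
            for x in _NUTRIENTS
        }
        for i in range(n_per_strip):
            rows.append(
                {
                    "strip": f"S{s + 1}",
                    "plot_in_strip": i + 1,
                    "soil_n": mean.sn * factors["n"][i],
                    "soil_p": mean.sp * factors["p"][i],
                    "soil_k": mean.sk * factors["k"][i],
                }
            )
    return pd.DataFrame(rows)


def _clean_uptake(
    truth: TruthParameters, stv: dict, dose: NutrientTriple, fym_rate: float
) -> dict:
    return {
        x: truth.cs_frac[x] * stv[x]
        + truth.cf_frac[x] * dose[x]
        + truth.com_pct[x] / 100.0 * fym_rate * 1000.0
        for x in _NUTRIENTS
    }


def simulate_main_experiment(
    truth: TruthParameters,
    design: DesignSpec | None = None,
    seed: int = 0,
    *,
    per_nutrient_consistency: bool = False,
) -> PlotTable:
    """Generate a full calibration PlotTable with known ground truth.

    In noiseless mode the calibrator recovers NR_N, CS, CF and COM exactly;
    with ``per_nutrient_consistency`` (and truth parameters that admit it)
    NR_P and NR_K are recovered exactly as well.
    """
    design = design or default_design()
    stv_table = simulate_gradient(truth, design, seed)
    rng = np.random.default_rng(seed + 1)

    records = []
    idx = 0
    for s in range(design.n_strips):
        strip = f"S{s + 1}"
        for b, fym_rate in enumerate(design.fym_levels):
            for dose in design.npk_subplot_doses:
                row = stv_table.iloc[idx]
                stv = {"n": row.soil_n, "p": row.soil_p, "k": row.soil_k}
                clean = _clean_uptake(truth, stv, dose, fym_rate)
                yield_clean = clean["n"] / truth.nr["n"]
                if per_nutrient_consistency:
                    for x in ("p", "k"):
                        clean[x] = truth.nr[x] * yield_clean
                        if truth.cs_frac[x] <= 0:
                            raise ValueError(
                                "per_nutrient_consistency requires cs_frac > 0"
                            )
                        solved = (
                            clean[x]
                            - truth.cf_frac[x] * dose[x]
                            - truth.com_pct[x] / 100.0 * fym_rate * 1000.0
                        ) / truth.cs_frac[x]
                        if solved < 0:
                            raise ValueError(
                                "inconsistent option combination: truth parameters "
                                f"leave no non-negative soil-test {x.upper()} on plot "
                                f"{strip}-F{b}-{idx}; disable per_nutrient_consistency "
                                "or reduce the manure/fertilizer credits"
                            )
                        stv[x] = solved
                e_u = _noise(rng, truth.uptake_noise_cv, 3, truth.noise_model)
                e_y = _noise(rng, truth.yield_noise_cv, 1, truth.noise_model)[0]
                uptake = NutrientTriple(
                    n=clean["n"] * e_u[0], p=clean["p"] * e_u[1], k=clean["k"] * e_u[2]
                )
                cob = yield_clean * e_y
                idx += 1
                records.append(
                    PlotRecord(
                        plot_id=f"P{idx:03d}",
                        strip=strip,
                        fym_block=f"F{b}",
                        fert_dose=dose,
                        fym_rate=fym_rate,
                        soil_test=SoilTest(sn=stv["n"], sp=stv["p"], sk=stv["k"]),
                        cob_yield=cob,
                        stover_yield=cob * truth.stover_ratio,
                        uptake=uptake,
                    )
                )
    meta = {
        "dose_basis": ELEMENTAL,
        "seed": str(seed),
        "generator": "stcr.synthetic.simulate_main_experiment",
    }
    return PlotTable(records=records, metadata=meta)


@dataclass(frozen=True)
class VerificationTreatment:
    """One verification-trial treatment specification.

    Either a yield target (doses computed from the supplied prescription
    equation) or fixed doses (comparator treatments, or the zero-dose
    absolute control).
    """

    treatment: str
    target_t: float | None = None
    doses: NutrientTriple | None = None
    fym_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.target_t is None and self.doses is None:
            raise ValueError(f"{self.treatment}: give a target or fixed doses")


def simulate_verification(
    truth: TruthParameters,
    equation: PrescriptionEquation | None,
    treatments: Sequence[VerificationTreatment],
    soil_test: SoilTest,
    seed: int = 0,
) -> list[TreatmentOutcome]:
    """Simulate a verification trial under the generator's uptake model.

    Targeted treatments get their doses from ``prescribe``; every outcome's
    uptake and yield follow the same contribution decomposition as the
    calibration generator.  A zero-dose control treatment must be included.
    """
    if not any(
        t.doses is not None and t.doses.total == 0 and t.fym_rate == 0
        for t in treatments
    ):
        raise ValueError("treatments must include a zero-dose, zero-FYM control")
    rng = np.random.default_rng(seed)
    out = []
    for t in treatments:
        if t.target_t is not None:
            if equation is None:
                raise ValueError(f"{t.treatment}: target given but no equation")
            rec = prescribe(equation, t.target_t, soil_test, t.fym_rate)
            doses = rec.dose
        else:
            doses = t.doses
        stv = {"n": soil_test.sn, "p": soil_test.sp, "k": soil_test.sk}
        clean = _clean_uptake(truth, stv, doses, t.fym_rate)
        yield_clean = clean["n"] / truth.nr["n"]
        e_u = _noise(rng, truth.uptake_noise_cv, 3, truth.noise_model)
        e_y = _noise(rng, truth.yield_noise_cv, 1, truth.noise_model)[0]
        uptake = NutrientTriple(
            n=clean["n"] * e_u[0], p=clean["p"] * e_u[1], k=clean["k"] * e_u[2]
        )
        cob = yield_clean * e_y
        cob_uptake = NutrientTriple(
            n=uptake.n * truth.cob_uptake_frac,
            p=uptake.p * truth.cob_uptake_frac,
            k=uptake.k * truth.cob_uptake_frac,
        )
        out.append(
            TreatmentOutcome(
                treatment=t.treatment,
                doses=doses,
                fym_rate=t.fym_rate,
                cob_yield=cob,
                stover_yield=cob * truth.stover_ratio,
                uptake=uptake,
                cob_uptake=cob_uptake,
                target_t=t.target_t,
            )
        )
    return out
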