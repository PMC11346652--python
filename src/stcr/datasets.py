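"""Bundled reference data: a published sweet-corn STCR study on an Alfisol.

Two small datasets ship with the package so the whole pipeline can be
exercised without any field data:

* ``reference_basic_parameters`` — the calibrated basic-parameter table of
  the reference system (NR kg/t, CS%, CF%, COM%) for both prescription
  modes, plus the post-gradient strip fertility means;
* ``verification_trial`` — the reference verification-trial outcomes: seven
  treatments (four STCR yield targets, the general recommended dose GRD, a
  soil-fertility-rating dose SFR, and the absolute control) with their
  elemental doses, fresh cob and dry stover yields and total NPK uptakes.

These are measured values from a real trial, so they are inputs to the
metric suite, not synthetic fixtures.
"""

from __future__ import annotations

from .calibration import MODE_NPK_ALONE, MODE_NPK_FYM, BasicParameters
from .evaluation import TreatmentOutcome
from .trial_data import NutrientTriple, SoilTest
from .units import ELEMENTAL, K_TO_K2O, P_TO_P2O5

__all__ = [
    "REFERENCE_PARAMS",
    "REFERENCE_STRIP_MEANS_OXIDE",
    "reference_basic_parameters",
    "reference_strip_means",
    "verification_trial",
    "GRD_OXIDE",
]

_NUTRIENTS = ("n", "p", "k")

# Calibrated basic parameters of the reference system.
REFERENCE_PARAMS = {
    MODE_NPK_ALONE: {
        "nr": {"n": 5.85, "p": 0.87, "k": 4.31},
        "cs": {"n": 29.53, "p": 7.73, "k": 44.03},
        "cf": {"n": 39.72, "p": 23.58, "k": 104.28},
        "com": None,
    },
    MODE_NPK_FYM: {
        "nr": {"n": 6.07, "p": 0.92, "k": 4.33},
        "cs": {"n": 29.53, "p": 7.73, "k": 44.03},
        "cf": {"n": 42.25, "p": 24.29, "k": 94.48},
        "com": {"n": 0.871, "p": 0.35, "k": 0.64},
    },
}

# Post-gradient strip fertility means, available N / P2O5 / K2O kg per ha.
REFERENCE_STRIP_MEANS_OXIDE = (
    (244.97, 97.87, 106.57),
    (292.56, 105.13, 135.52),
    (320.16, 107.09, 161.46),
)

# Regional general recommended dose, N:P2O5:K2O kg/ha.
GRD_OXIDE = (150.0, 75.0, 40.0)


def reference_basic_parameters(mode: str = MODE_NPK_ALONE) -> BasicParameters:
    """The reference system's calibrated parameters for one mode."""
    if mode not in REFERENCE_PARAMS:
        raise ValueError(f"unknown mode {mode!r}")
    ref = REFERENCE_PARAMS[mode]
    return BasicParameters.from_values(
        mode=mode, nr=ref["nr"], cs_pct=ref["cs"], cf_pct=ref["cf"], com_pct=ref["com"]
    )


def reference_strip_means(basis: str = ELEMENTAL) -> tuple[SoilTest, ...]:
    """Strip fertility means as SoilTest objects on the requested basis."""
    out = []
    for n, p2o5, k2o in REFERENCE_STRIP_MEANS_OXIDE:
        st = SoilTest(sn=n, sp=p2o5 / P_TO_P2O5, sk=k2o / K_TO_K2O, basis=ELEMENTAL)
        out.append(st.to_basis(basis))
    return tuple(out)


# Verification-trial outcomes: (doses N/P/K elemental kg/ha, FYM t/ha,
# fresh cob t/ha, dry stover t/ha, uptake N/P/K kg/ha, yield target t/ha).
_VERIFICATION_ROWS = {
    "T1": ((210.21, 15.70, 16.69), 0.0, 23.21, 34.81, (181.04, 13.79, 119.44), 25.0),
    "T2": ((184.02, 13.49, 10.43), 10.0, 23.38, 35.07, (182.35, 14.71, 120.31), 25.0),
    "T3": ((146.36, 9.67, 11.92), 0.0, 21.46, 32.19, (167.40, 12.75, 110.44), 22.0),
    "T4": ((136.95, 9.13, 6.46), 10.0, 22.34, 33.51, (174.26, 13.93, 114.96), 22.0),
    "T5": ((150.00, 33.00, 33.20), 0.0, 21.52, 32.28, (167.86, 12.47, 110.75), None),
    "T6": ((187.50, 27.50, 33.20), 0.0, 22.69, 34.03, (176.96, 13.48, 116.75), None),
    "T7": ((0.0, 0.0, 0.0), 0.0, 6.86, 10.29, (68.59, 5.49, 35.29), None),
}


def verification_trial() -> list[TreatmentOutcome]:
    """The seven reference verification-trial treatment outcomes.

    T1/T3: STCR NPK-alone targets 25/22 t/ha; T2/T4: STCR NPK+FYM targets
    25/22 t/ha; T5: GRD; T6: soil fertility rating; T7: absolute control.
    Cob-only uptakes were not reported, so ``cob_uptake`` is None.
    """
    out = []
    for tid, (dose, fym, cob, stover, uptake, target) in _VERIFICATION_ROWS.items():
        out.append(
            TreatmentOutcome(
                treatment=tid,
                doses=NutrientTriple(*dose, basis=ELEMENTAL),
                fym_rate=fym,
                cob_yield=cob,
                stover_yield=stover,
                uptake=NutrientTriple(*uptake),
                cob_uptake=None,
                target_t=target,
            )
        )
    return out
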