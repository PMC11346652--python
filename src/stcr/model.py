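"""Model/Results front end for the targeted-yield calibration.

`TargetedYieldModel` wraps a calibration plot table the way a regression
model wraps a design matrix: construct it from a `PlotTable`, a DataFrame,
or a CSV file, call :meth:`fit`, and receive a `TargetedYieldResults`
holding the calibrated basic parameters, bootstrap uncertainties, the
diagnostic summaries, and the downstream operations (deriving prescription
equations, prescribing doses, plotting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration
from .calibration import (
    MODE_NPK_ALONE,
    MODE_NPK_FYM,
    BasicParameters,
    SelectionPolicy,
    calibrate,
    strip_summary,
    yield_dose_uptake_correlation,
)
from .prescription import DoseRecommendation, PrescriptionEquation, derive_equation, prescribe
from .trial_data import (
    NutrientTriple,
    PlotRecord,
    PlotTable,
    SoilTest,
    read_plot_table,
)
from .units import ELEMENTAL

__all__ = ["TargetedYieldModel", "TargetedYieldResults"]

_NUTRIENTS = ("n", "p", "k")
_PARAMS = ("nr", "cs_pct", "cf_pct", "com_pct")


def _table_from_dataframe(df: pd.DataFrame, metadata: dict | None = None) -> PlotTable:
    records = []
    for row in df.itertuples(index=False):
        uptake = None
        if not (pd.isna(row.uptake_n) or pd.isna(row.uptake_p) or pd.isna(row.uptake_k)):
            uptake = NutrientTriple(n=row.uptake_n, p=row.uptake_p, k=row.uptake_k)
        records.append(
            PlotRecord(
                plot_id=str(row.plot_id),
                strip=str(row.strip),
                fym_block=str(row.fym_block),
                fert_dose=NutrientTriple(n=row.dose_n, p=row.dose_p, k=row.dose_k),
                fym_rate=float(row.fym_rate),
                soil_test=SoilTest(sn=row.soil_n, sp=row.soil_p, sk=row.soil_k),
                cob_yield=float(row.cob_yield),
                stover_yield=float(row.stover_yield),
                uptake=uptake,
            )
        )
    return PlotTable(records=records, metadata=dict(metadata or {"dose_basis": ELEMENTAL}))


class TargetedYieldModel:
    """Targeted-yield (STCR) calibration model over a plot table."""

    def __init__(
        self,
        table: PlotTable,
        mode: str = MODE_NPK_ALONE,
        *,
        policy: SelectionPolicy | None = None,
    ) -> None:
        if mode not in (MODE_NPK_ALONE, MODE_NPK_FYM):
            raise ValueError(f"unknown mode {mode!r}")
        self.table = table
        self.mode = mode
        self.policy = policy or SelectionPolicy()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, mode: str = MODE_NPK_ALONE, **kwargs
    ) -> "TargetedYieldModel":
        return cls(_table_from_dataframe(df), mode=mode, **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, mode: str = MODE_NPK_ALONE, **read_kwargs
    ) -> "TargetedYieldModel":
        return cls(read_plot_table(path, **read_kwargs), mode=mode)

    def fit(
        self, *, bootstrap: int = 0, seed: int | None = None
    ) -> "TargetedYieldResults":
        """Calibrate the basic parameters.

        ``bootstrap`` > 0 resamples plots within each role class to attach
        standard errors to every parameter estimate.
        """
        params = calibrate(self.table, self.mode, policy=self.policy)
        bse = None
        if bootstrap > 0:
            bse = self._bootstrap_se(bootstrap, seed)
        return TargetedYieldResults(model=self, params=params, bse=bse)

    def _bootstrap_se(self, n_boot: int, seed: int | None) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        by_role: dict[str, list[PlotRecord]] = {}
        for r in self.table:
            by_role.setdefault(r.role, []).append(r)
        draws: list[dict] = []
        for _ in range(n_boot):
            records = []
            for role_records in by_role.values():
                idx = rng.integers(0, len(role_records), size=len(role_records))
                records.extend(role_records[i] for i in idx)
            resampled = PlotTable(
                records=[
                    # re-key ids to keep the uniqueness invariant
                    PlotRecord(
                        plot_id=f"B{j:04d}",
                        strip=r.strip,
                        fym_block=r.fym_block,
                        fert_dose=r.fert_dose,
                        fym_rate=r.fym_rate,
                        soil_test=r.soil_test,
                        cob_yield=r.cob_yield,
                        stover_yield=r.stover_yield,
                        uptake=r.uptake,
                    )
                    for j, r in enumerate(records)
                ],
                metadata=self.table.metadata,
            )
            try:
                bp = calibrate(resampled, self.mode, policy=self.policy)
            except ValueError:
                continue
            row = {}
            for x in _NUTRIENTS:
                row[f"nr_{x}"] = bp[x].nr
                row[f"cs_pct_{x}"] = bp[x].cs_pct
                row[f"cf_pct_{x}"] = bp[x].cf_pct
                if self.mode == MODE_NPK_FYM:
                    row[f"com_pct_{x}"] = bp[x].com_pct
            draws.append(row)
        return pd.DataFrame(draws).std(ddof=1).to_frame("bse")


@dataclass
class TargetedYieldResults:
    """Fitted basic parameters plus diagnostics and downstream operations."""

    model: TargetedYieldModel
    params: BasicParameters
    bse: pd.DataFrame | None = None

    @property
    def mode(self) -> str:
        return self.params.mode

    # -- downstream operations -------------------------------------------
    def prescription_equation(self, **derive_kwargs) -> PrescriptionEquation:
        return derive_equation(self.params, **derive_kwargs)

    def prescribe(
        self,
        target_t: float,
        soil_test: SoilTest,
        fym_rate: float = 0.0,
        **derive_kwargs,
    ) -> DoseRecommendation:
        eq = self.prescription_equation(**derive_kwargs)
        return prescribe(eq, target_t, soil_test, fym_rate)

    # -- diagnostics ------------------------------------------------------
    def strip_summary(self, variable: str) -> pd.DataFrame:
        return pd.DataFrame(
            [s.__dict__ for s in strip_summary(self.model.table, variable)]
        ).set_index("strip")

    def yield_correlations(self) -> pd.DataFrame:
        return yield_dose_uptake_correlation(self.model.table)

    def summary(self) -> str:
        """Text summary of the calibrated parameter grid."""
        df = self.params.to_dataframe()
        lines = [
            "Targeted-yield calibration results",
            "==================================",
            f"mode: {self.mode}    plots: {len(self.model.table)}",
            f"plots per estimate: {self.params.n_plots_used}",
            "",
            df.round(3).to_string(),
        ]
        if self.bse is not None:
            lines += ["", "bootstrap standard errors:", self.bse.round(4).to_string()]
        eq = self.prescription_equation()
        lines += ["", eq.summary()]
        return "\n".join(lines)

    def plot_yield_correlations(self, ax=None):
        """Scatter cob yield against each nutrient uptake with the OLS fit."""
        import matplotlib.pyplot as plt

        corr = self.yield_correlations()
        df = self.model.table.to_dataframe()
        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 4))
        else:
            axes = ax
        for a, x in zip(np.atleast_1d(axes), _NUTRIENTS):
            col = f"uptake_{x}"
            a.scatter(df[col], df["cob_yield"], s=12)
            row = corr.loc[col]
            xs = np.linspace(df[col].min(), df[col].max(), 50)
            # plotted line is yield on uptake, matching the regression
            a.plot(xs, row["intercept"] + row["slope"] * xs, color="C1")
            a.set_xlabel(f"{x.upper()} uptake (kg/ha)")
            a.set_ylabel("fresh cob yield (t/ha)")
            a.set_title(f"r$^2$ = {row['r2']:.3f}")
        return axes
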