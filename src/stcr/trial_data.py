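"""Domain types and delimited-text I/O for STCR trial plot tables.

A calibration (main-experiment) trial is a table of plots, each carrying its
design factors (fertility strip, manure block), applied fertilizer doses and
farm-yard-manure rate, pre-sowing soil test values, yields, and nutrient
uptakes.  This module defines the validated record types, plot-role
inference, the uptake-from-tissue-analysis arithmetic, and a lossless CSV
round trip with a documented column dictionary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .units import ELEMENTAL, OXIDE, check_basis, convert_value

__all__ = [
    "NutrientTriple",
    "SoilTest",
    "PlotRecord",
    "PlotTable",
    "FymComposition",
    "ROLE_CONTROL",
    "ROLE_NPK_ONLY",
    "ROLE_FYM_ONLY",
    "ROLE_NPK_PLUS_FYM",
    "infer_role",
    "uptake_from_concentration",
    "fym_nutrients",
    "convert_basis",
    "read_plot_table",
    "write_table",
    "COLUMN_SYNONYMS",
]

ROLE_CONTROL = "control"
ROLE_NPK_ONLY = "npk_only"
ROLE_FYM_ONLY = "fym_only"
ROLE_NPK_PLUS_FYM = "npk_plus_fym"
_ROLES = (ROLE_CONTROL, ROLE_NPK_ONLY, ROLE_FYM_ONLY, ROLE_NPK_PLUS_FYM)

_UNITS = ("kg_per_ha", "kg_per_t", "percent")


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _require_nonneg(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class NutrientTriple:
    """An (N, P, K) quantity with an explicit unit and P/K basis.

    ``basis`` applies to P and K only; N is identical under both bases.
    Quantities in kg_per_ha / kg_per_t must be non-negative unless ``raw=True``
    flags a pre-clamp prescription output, which may legitimately be negative.
    """

    n: float
    p: float
    k: float
    basis: str = ELEMENTAL
    unit: str = "kg_per_ha"
    raw: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", check_basis(self.basis))
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")
        for name in ("n", "p", "k"):
            v = _require_finite(name, getattr(self, name))
            if not self.raw and self.unit in ("kg_per_ha", "kg_per_t") and v < 0:
                raise ValueError(f"{name} must be >= 0 in unit {self.unit}, got {v}")
            object.__setattr__(self, name, v)

    def __getitem__(self, nutrient: str) -> float:
        return {"n": self.n, "p": self.p, "k": self.k}[nutrient.lower()]

    def to_basis(self, target_basis: str) -> "NutrientTriple":
        return convert_basis(self, target_basis)

    @property
    def total(self) -> float:
        return self.n + self.p + self.k


@dataclass(frozen=True)
class SoilTest:
    """Pre-sowing available-nutrient soil test values in kg/ha.

    sn/sp/sk are available N (alkaline permanganate), P (Bray) and
    K (ammonium acetate).  Conventionally these are elemental, but published
    summaries sometimes label them P2O5/K2O, so the basis must be declared.
    """

    sn: float
    sp: float
    sk: float
    basis: str = ELEMENTAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", check_basis(self.basis))
        for name in ("sn", "sp", "sk"):
            object.__setattr__(self, name, _require_nonneg(name, getattr(self, name)))

    def __getitem__(self, nutrient: str) -> float:
        return {"n": self.sn, "p": self.sp, "k": self.sk}[nutrient.lower()]

    def to_basis(self, target_basis: str) -> "SoilTest":
        target_basis = check_basis(target_basis)
        return SoilTest(
            sn=self.sn,
            sp=convert_value(self.sp, "p", self.basis, target_basis),
            sk=convert_value(self.sk, "k", self.basis, target_basis),
            basis=target_basis,
        )


@dataclass(frozen=True)
class FymComposition:
    """Total N/P/K content of farm yard manure, % of fresh weight."""

    n_pct: float
    p_pct: float
    k_pct: float

    def __post_init__(self) -> None:
        for name in ("n_pct", "p_pct", "k_pct"):
            v = _require_nonneg(name, getattr(self, name))
            if v > 100:
                raise ValueError(f"{name} must be <= 100, got {v}")
            object.__setattr__(self, name, v)


def infer_role(fert_dose: NutrientTriple, fym_rate: float) -> str:
    """Classify a plot from its dose/FYM pattern.

    control: no fertilizer, no FYM; fym_only: FYM without fertilizer;
    npk_only: fertilizer without FYM; npk_plus_fym: both.  The patterns are
    mutually exclusive, so inference never ties.
    """
    has_npk = fert_dose.n > 0 or fert_dose.p > 0 or fert_dose.k > 0
    has_fym = fym_rate > 0
    if has_npk and has_fym:
        return ROLE_NPK_PLUS_FYM
    if has_npk:
        return ROLE_NPK_ONLY
    if has_fym:
        return ROLE_FYM_ONLY
    return ROLE_CONTROL


@dataclass(frozen=True)
class PlotRecord:
    """One calibration or verification plot."""

    plot_id: str
    strip: str
    fym_block: str
    fert_dose: NutrientTriple
    fym_rate: float
    soil_test: SoilTest
    cob_yield: float
    stover_yield: float
    uptake: NutrientTriple | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fym_rate", _require_nonneg("fym_rate", self.fym_rate))
        object.__setattr__(self, "cob_yield", _require_nonneg("cob_yield", self.cob_yield))
        object.__setattr__(
            self, "stover_yield", _require_nonneg("stover_yield", self.stover_yield)
        )
        inferred = infer_role(self.fert_dose, self.fym_rate)
        if self.role is None:
            object.__setattr__(self, "role", inferred)
        elif self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        elif self.role != inferred:
            raise ValueError(
                f"plot {self.plot_id}: declared role {self.role!r} contradicts "
                f"dose/FYM pattern (inferred {inferred!r})"
            )


@dataclass
class PlotTable:
    """Ordered collection of plots plus free-form metadata.

    Metadata should declare the dose basis ('dose_basis') for P/K columns;
    crop and season keys are conventional but optional.
    """

    records: list[PlotRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.plot_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlotRecord]:
        return iter(self.records)

    def select(self, role: str | None = None, strip: str | None = None) -> list[PlotRecord]:
        out = list(self.records)
        if role is not None:
            out = [r for r in out if r.role == role]
        if strip is not None:
            out = [r for r in out if r.strip == strip]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "plot_id": r.plot_id,
                "strip": r.strip,
                "fym_block": r.fym_block,
                "dose_n": r.fert_dose.n,
                "dose_p": r.fert_dose.p,
                "dose_k": r.fert_dose.k,
                "fym_rate": r.fym_rate,
                "soil_n": r.soil_test.sn,
                "soil_p": r.soil_test.sp,
                "soil_k": r.soil_test.sk,
                "cob_yield": r.cob_yield,
                "stover_yield": r.stover_yield,
                "uptake_n": r.uptake.n if r.uptake is not None else float("nan"),
                "uptake_p": r.uptake.p if r.uptake is not None else float("nan"),
                "uptake_k": r.uptake.k if r.uptake is not None else float("nan"),
                "role": r.role,
            }
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Arithmetic helpers

def uptake_from_concentration(content_pct: float, dry_weight: float) -> float:
    """Nutrient uptake (kg/ha) from tissue concentration and dry matter.

    uptake = content% x dry weight (kg/ha) / 100.
    """
    content_pct = _require_finite("content_pct", content_pct)
    dry_weight = _require_finite("dry_weight", dry_weight)
    if not 0 <= content_pct <= 100:
        raise ValueError(f"content_pct must be in [0, 100], got {content_pct}")
    if dry_weight < 0:
        raise ValueError(f"dry_weight must be >= 0, got {dry_weight}")
    return content_pct * dry_weight / 100.0


def fym_nutrients(fym_rate: float, comp: FymComposition) -> NutrientTriple:
    """Nutrients (kg/ha, elemental) supplied by ``fym_rate`` t/ha of manure."""
    fym_rate = _require_nonneg("fym_rate", fym_rate)
    kg = fym_rate * 1000.0
    return NutrientTriple(
        n=kg * comp.n_pct / 100.0,
        p=kg * comp.p_pct / 100.0,
        k=kg * comp.k_pct / 100.0,
        basis=ELEMENTAL,
    )


def convert_basis(x: NutrientTriple, target_basis: str) -> NutrientTriple:
    """Convert a triple between elemental and oxide bases (N unchanged)."""
    target_basis = check_basis(target_basis)
    if target_basis == x.basis:
        return x
    return NutrientTriple(
        n=x.n,
        p=convert_value(x.p, "p", x.basis, target_basis),
        k=convert_value(x.k, "k", x.basis, target_basis),
        basis=target_basis,
        unit=x.unit,
        raw=x.raw,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Column dictionary: canonical name -> accepted (case-insensitive) synonyms.
# Unknown extra columns are preserved in table metadata.

COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "plot_id": ("plot_id", "plot", "id"),
    "strip": ("strip", "fertility_strip"),
    "fym_block": ("fym_block", "manure_block", "block"),
    "dose_n": ("dose_n", "fert_n", "n_dose", "fn"),
    "dose_p": ("dose_p", "fert_p", "p_dose", "fp"),
    "dose_k": ("dose_k", "fert_k", "k_dose", "fk"),
    "fym_rate": ("fym_rate", "fym", "fym_t_ha"),
    "soil_n": ("soil_n", "sn", "stv_n", "avail_n"),
    "soil_p": ("soil_p", "sp", "stv_p", "avail_p"),
    "soil_k": ("soil_k", "sk", "stv_k", "avail_k"),
    "cob_yield": ("cob_yield", "cob_yield_t_ha", "fcy", "fresh_cob_yield"),
    "stover_yield": ("stover_yield", "stover_yield_t_ha", "dsy", "dry_stover_yield"),
    "uptake_n": ("uptake_n", "n_uptake", "total_n_uptake"),
    "uptake_p": ("uptake_p", "p_uptake", "total_p_uptake"),
    "uptake_k": ("uptake_k", "k_uptake", "total_k_uptake"),
    "conc_n": ("conc_n", "n_pct", "n_content_pct"),
    "conc_p": ("conc_p", "p_pct", "p_content_pct"),
    "conc_k": ("conc_k", "k_pct", "k_content_pct"),
    "dry_weight": ("dry_weight", "dry_matter_kg_ha", "dm_kg_ha"),
    "role": ("role", "treatment_role"),
}

_MANDATORY = (
    "plot_id",
    "strip",
    "fym_block",
    "dose_n",
    "dose_p",
    "dose_k",
    "fym_rate",
    "soil_n",
    "soil_p",
    "soil_k",
    "cob_yield",
    "stover_yield",
)

_NUMERIC = tuple(c for c in _MANDATORY if c not in ("plot_id", "strip", "fym_block")) + (
    "uptake_n",
    "uptake_p",
    "uptake_k",
    "conc_n",
    "conc_p",
    "conc_k",
    "dry_weight",
)


def _canonicalise_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical names via the synonym dictionary."""
    lookup = {syn: canon for canon, syns in COLUMN_SYNONYMS.items() for syn in syns}
    return {raw: lookup.get(str(raw).strip().lower(), str(raw)) for raw in columns}


def read_plot_table(
    path: str | Path,
    *,
    sep: str = ",",
    dose_basis: str | None = None,
    metadata: Mapping[str, str] | None = None,
) -> PlotTable:
    """Read a plot table from delimited text.

    ``dose_basis`` declares the basis of the P/K dose and soil-test columns;
    it may instead come from a ``dose_basis`` value in ``metadata``.  Doses
    and soil tests are converted to the canonical elemental basis on load.
    Uptake may be given directly or via tissue concentrations + dry weight,
    in which case it is computed on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plot table not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df = df.rename(columns=_canonicalise_columns(df.columns))

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    meta = dict(metadata or {})
    basis = dose_basis or meta.get("dose_basis") or ELEMENTAL
    basis = check_basis(basis)
    meta["dose_basis"] = ELEMENTAL  # canonical after load
    meta["source_dose_basis"] = basis
    extra = [c for c in df.columns if c not in COLUMN_SYNONYMS]
    if extra:
        meta["extra_columns"] = ",".join(extra)

    def cell(row_idx: int, col: str) -> float:
        rawv = df.at[row_idx, col]
        if rawv is None or (isinstance(rawv, float) and math.isnan(rawv)) or str(rawv) == "":
            raise ValueError(f"{path} row {row_idx + 2}: missing value in column {col!r}")
        try:
            return float(rawv)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {row_idx + 2}: non-numeric value {rawv!r} in column {col!r}"
            ) from None

    records: list[PlotRecord] = []
    has_uptake = all(c in df.columns for c in ("uptake_n", "uptake_p", "uptake_k"))
    has_conc = all(
        c in df.columns for c in ("conc_n", "conc_p", "conc_k", "dry_weight")
    )
    for i in df.index:
        try:
            dose = NutrientTriple(
                n=cell(i, "dose_n"), p=cell(i, "dose_p"), k=cell(i, "dose_k"), basis=basis
            ).to_basis(ELEMENTAL)
            soil = SoilTest(
                sn=cell(i, "soil_n"), sp=cell(i, "soil_p"), sk=cell(i, "soil_k"), basis=basis
            ).to_basis(ELEMENTAL)
            uptake: NutrientTriple | None = None
            if has_uptake and not any(
                pd.isna(df.at[i, c]) for c in ("uptake_n", "uptake_p", "uptake_k")
            ):
                uptake = NutrientTriple(
                    n=cell(i, "uptake_n"), p=cell(i, "uptake_p"), k=cell(i, "uptake_k")
                )
            elif has_conc:
                dw = cell(i, "dry_weight")
                uptake = NutrientTriple(
                    n=uptake_from_concentration(cell(i, "conc_n"), dw),
                    p=uptake_from_concentration(cell(i, "conc_p"), dw),
                    k=uptake_from_concentration(cell(i, "conc_k"), dw),
                )
            role = None
            if "role" in df.columns and not pd.isna(df.at[i, "role"]):
                role = str(df.at[i, "role"]).strip().lower()
            records.append(
                PlotRecord(
                    plot_id=str(df.at[i, "plot_id"]).strip(),
                    strip=str(df.at[i, "strip"]).strip(),
                    fym_block=str(df.at[i, "fym_block"]).strip(),
                    fert_dose=dose,
                    fym_rate=cell(i, "fym_rate"),
                    soil_test=soil,
                    cob_yield=cell(i, "cob_yield"),
                    stover_yield=cell(i, "stover_yield"),
                    uptake=uptake,
                    role=role,
                )
            )
        except ValueError as exc:
            if f"row {i + 2}" in str(exc):
                raise
            raise ValueError(f"{path} row {i + 2}: {exc}") from exc
    return PlotTable(records=records, metadata=meta)


def write_table(table: PlotTable | pd.DataFrame, path: str | Path, *, sep: str = ",") -> Path:
    """Write a plot table (or any DataFrame result) to delimited text.

    Plot tables round-trip: ``read_plot_table(write_table(t))`` reproduces
    every field.  Full float precision is preserved via repr formatting.
    """
    path = Path(path)
    df = table.to_dataframe() if isinstance(table, PlotTable) else table
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path
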