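"""Readers/writers for the CSV dialects shared by the analysis modules.

All tables are UTF-8 CSV with a header row and period decimal separator.
Parse problems are reported with 1-based data row numbers (header = row
0).  Numeric output keeps >= 6 significant digits; display rounding is a
presentation concern.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .conformer_thermo import ConformerPoint, ConformerSeries, conformer_ratio
from .equilibrium import SolutionConditions
from .itc_binding import ITCProtocol, Isotherm
from .nmr_titration import NUCLEI, TitrationDataset, TitrationPoint

__all__ = [
    "TableFormatError",
    "read_titration_csv",
    "write_titration_csv",
    "read_conformer_csv",
    "write_conformer_csv",
    "read_isotherm_csv",
    "write_isotherm_csv",
]

_FLOAT_FMT = "%.8g"


class TableFormatError(ValueError):
    """Malformed tabular input; message carries file and row context."""


def _read_csv(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    try:
        df = pd.read_csv(p)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{p}: file is empty") from exc
    if df.empty:
        raise TableFormatError(f"{p}: no data rows")
    return df

def _numeric(df: pd.DataFrame, col: str, path, allow_blank: bool = False) -> pd.Series:
    if col not in df.columns:
        raise TableFormatError(f"{path}: missing mandatory column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise TableFormatError(
            f"{path}: row {row}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}"
        )
    if not allow_blank and vals.isna().any():
        row = int(vals.isna().idxmax()) + 1
        raise TableFormatError(f"{path}: row {row}: blank value in mandatory column {col!r}")
    return vals


# -- titration tables -------------------------------------------------------


def read_titration_csv(
    path: str | Path,
    conditions_template: SolutionConditions,
    nuclei: tuple[str, ...] | None = None,
) -> TitrationDataset:
    """Columns: ``ph``, one column per nucleus (blank = missing),
    optional ``weight``."""
    df = _read_csv(path)
    ph = _numeric(df, "ph", path)
    if nuclei is None:
        nuclei = tuple(c for c in df.columns if c not in ("ph", "weight"))
    if not nuclei:
        raise TableFormatError(f"{path}: no nucleus columns found")
    shifts = {nuc: _numeric(df, nuc, path, allow_blank=True) for nuc in nuclei}
    weights = (
        _numeric(df, "weight", path) if "weight" in df.columns else pd.Series(np.ones(len(df)))
    )
    points = []
    for i in range(len(df)):
        observed = {
            nuc: float(col[i]) for nuc, col in shifts.items() if not math.isnan(col[i])
        }
        if not observed:
            raise TableFormatError(f"{path}: row {i + 1}: no observed shifts")
        points.append(TitrationPoint(ph=float(ph[i]), observed=observed, weight=float(weights[i])))
    return TitrationDataset(
        points=tuple(points), nuclei=tuple(nuclei), conditions_template=conditions_template
    )


def write_titration_csv(dataset: TitrationDataset, path: str | Path) -> None:
    rows = []
    for p in dataset.points:
        row = {"ph": p.ph}
        row.update({nuc: p.observed.get(nuc, np.nan) for nuc in dataset.nuclei})
        row["weight"] = p.weight
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- conformer series -------------------------------------------------------


def read_conformer_csv(path: str | Path) -> ConformerSeries:
    """Columns: ``temperature_K``, ``ax_integral``, ``eq_integral``,
    optional ``replicate`` and ``impurity_correction`` (applied to the
    equatorial peak)."""
    df = _read_csv(path)
    t = _numeric(df, "temperature_K", path)
    ax = _numeric(df, "ax_integral", path)
    eq = _numeric(df, "eq_integral", path)
    rep = (
        _numeric(df, "replicate", path) if "replicate" in df.columns
        else pd.Series(np.ones(len(df)))
    )
    imp = (
        _numeric(df, "impurity_correction", path) if "impurity_correction" in df.columns
        else pd.Series(np.zeros(len(df)))
    )
    points = []
    for i in range(len(df)):
        try:
            k = conformer_ratio(float(ax[i]), float(eq[i]), float(imp[i])).k_ax_eq
            points.append(
                ConformerPoint(temperature_k=float(t[i]), k_ax_eq=k, replicate=int(rep[i]))
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: row {i + 1}: {exc}") from exc
    return ConformerSeries(tuple(points))


def write_conformer_csv(series: ConformerSeries, path: str | Path) -> None:
    """Writes k values back out as unit-eq_integral rows (lossless for K)."""
    rows = [
        {
            "temperature_K": p.temperature_k,
            "ax_integral": p.k_ax_eq,
            "eq_integral": 1.0,
            "replicate": p.replicate,
        }
        for p in series.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# -- ITC isotherms ----------------------------------------------------------


def read_isotherm_csv(path: str | Path, protocol: ITCProtocol | None = None) -> Isotherm:
    """Columns: ``injection``, ``volume_uL``, ``heat_kcal_per_mol``,
    optional ``molar_ratio`` (recomputed from ``protocol`` when given)."""
    df = _read_csv(path)
    _numeric(df, "injection", path)
    vol = _numeric(df, "volume_uL", path)
    heat = _numeric(df, "heat_kcal_per_mol", path)
    if protocol is not None:
        mt, xt = protocol.cell_concentrations()
        if len(df) != protocol.n_injections:
            raise TableFormatError(
                f"{path}: {len(df)} rows but protocol has {protocol.n_injections} injections"
            )
        mr = xt / mt
    elif "molar_ratio" in df.columns:
        mr = _numeric(df, "molar_ratio", path).to_numpy()
    else:
        raise TableFormatError(
            f"{path}: need a molar_ratio column or an explicit protocol"
        )
    return Isotherm(
        molar_ratio=np.asarray(mr, dtype=float),
        heat_kcal_per_mol=heat.to_numpy(),
        injection_volumes_ul=tuple(float(v) for v in vol),
    )


def write_isotherm_csv(isotherm: Isotherm, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(isotherm) + 1),
            "volume_uL": isotherm.injection_volumes_ul,
            "molar_ratio": isotherm.molar_ratio,
            "heat_kcal_per_mol": isotherm.heat_kcal_per_mol,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
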