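"""Delimited-text I/O for spectra and yield tables.

Two tabular dialects are accepted for spectra:

* wide  — one row per plot; columns ``genotype,treatment,year,rep`` then
  one column per integer wavelength (``350``, ``351``, ... ``2500``);
* long  — columns ``genotype,treatment,year,rep,wavelength_nm,reflectance``.

Yield tables use columns ``genotype,treatment,year,rep,gy_t_ha`` with
grain yield in t/ha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import SpectraSet, SpectrumRecord, WavelengthGrid, build_grid

KEY_COLS = ["genotype", "treatment", "year", "rep"]
YIELD_COL = "gy_t_ha"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spectra(path, grid: WavelengthGrid | None = None) -> SpectraSet:
    """Read a spectra table (wide or long dialect, auto-detected)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in KEY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra file lacks key columns {missing}")
    if {"wavelength_nm", "reflectance"} <= set(df.columns):
        return _from_long(df, grid)
    return _from_wide(df, grid)


def _wavelength_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if str(c).strip().lstrip("-").isdigit()]


def _from_wide(df: pd.DataFrame, grid: WavelengthGrid | None) -> SpectraSet:
    wl_cols = _wavelength_columns(df)
    if not wl_cols:
        raise ValueError("wide spectra file has no integer wavelength columns")
    wl = np.array(sorted(int(c) for c in wl_cols))
    step = int(np.diff(wl)[0]) if len(wl) > 1 else 1
    if grid is None:
        grid = build_grid(int(wl[0]), int(wl[-1]), step)
    ordered = [str(w) if str(w) in df.columns else w for w in wl]
    records = []
    for _, row in df.iterrows():
        records.append(
            SpectrumRecord(
                genotype=str(row["genotype"]),
                treatment=str(row["treatment"]),
                year=int(row["year"]),
                replicate=int(row["rep"]),
                reflectance=row[ordered].to_numpy(dtype=float),
                grid=grid,
            )
        )
    return SpectraSet(grid=grid, records=records)


def _from_long(df: pd.DataFrame, grid: WavelengthGrid | None) -> SpectraSet:
    wl = np.sort(df["wavelength_nm"].unique().astype(int))
    step = int(np.diff(wl)[0]) if len(wl) > 1 else 1
    if grid is None:
        grid = build_grid(int(wl[0]), int(wl[-1]), step)
    records = []
    for key, sub in df.groupby(KEY_COLS, sort=False):
        sub = sub.sort_values("wavelength_nm")
        records.append(
            SpectrumRecord(
                genotype=str(key[0]),
                treatment=str(key[1]),
                year=int(key[2]),
                replicate=int(key[3]),
                reflectance=sub["reflectance"].to_numpy(dtype=float),
                grid=grid,
            )
        )
    return SpectraSet(grid=grid, records=records)


def spectra_to_frame(spectra: SpectraSet) -> pd.DataFrame:
    """Wide DataFrame: key columns then one column per wavelength."""
    wl = spectra.grid.wavelengths
    rows = []
    for rec in spectra:
        row = dict(zip(KEY_COLS, rec.key))
        row.update({str(w): v for w, v in zip(wl, rec.reflectance)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_spectra(spectra: SpectraSet, path) -> None:
    spectra_to_frame(spectra).to_csv(path, sep=_sep_for(path), index=False)


def read_yields(path) -> pd.DataFrame:
    """Read a plot-level grain-yield table."""
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = KEY_COLS + [YIELD_COL]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"yield file lacks columns {missing}")
    if (df[YIELD_COL] <= 0).any():
        raise ValueError("grain yields must be positive")
    return df[needed].copy()


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep_for(path), index=index)
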