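"""Yield-based stress tolerance indices (STIs).

Given each genotype's grain yield under the control (GYc) and salinity
(GYs) treatments, five classical indices quantify tolerance:

* ``YSI = GYs / GYc`` — yield stability index (high = stable under stress);
* ``SSI = (1 - GYs/GYc) / (1 - GȲs/GȲc)`` — stress susceptibility index,
  the genotype's relative yield reduction scaled by the population's;
* ``STI = (GYc * GYs) / GȲc²`` — stress tolerance index (Fernandez), high
  for genotypes combining high potential yield and stress yield;
* ``TOL = GYc - GYs`` — tolerance index, the absolute yield loss;
* ``GMP = sqrt(GYc * GYs)`` — geometric mean productivity.

GȲc and GȲs are the grand means over all genotypes.  Per-genotype GYc /
GYs are means over years and replicates before the indices are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import math

import pandas as pd

from .io import YIELD_COL

STI_FEATURES = ("GYc", "GYs", "YSI", "SSI", "STI", "TOL", "GMP")


@dataclass(frozen=True)
class PopulationMeans:
    """Grand mean grain yields over all genotypes (t/ha)."""

    mean_gyc: float
    mean_gys: float

    def __post_init__(self):
        if self.mean_gyc <= 0 or self.mean_gys <= 0:
            raise ValueError("population mean yields must be positive")
        if self.mean_gys > self.mean_gyc:
            warnings.warn(
                "mean yield under salinity exceeds the control mean; "
                "SSI will have a negative denominator",
                stacklevel=2,
            )


@dataclass(frozen=True)
class STIRow:
    """One genotype's mean yields and the five tolerance indices."""

    genotype: str
    gyc: float
    gys: float
    ysi: float
    ssi: float
    sti: float
    tol: float
    gmp: float


def genotype_mean_yields(yields: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean GYc and GYs over years and replicates.

    Genotypes missing either treatment are dropped with a warning.
    """
    if yields.empty:
        raise ValueError("empty yield table")
    wide = (
        yields.groupby(["genotype", "treatment"])[YIELD_COL]
        .mean()
        .unstack("treatment")
    )
    for col in ("control", "salinity"):
        if col not in wide.columns:
            wide[col] = float("nan")
    incomplete = wide.index[wide[["control", "salinity"]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"genotypes missing a treatment excluded: {list(incomplete)}",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    if wide.empty:
        raise ValueError("no genotype has both treatments")
    out = wide.rename(columns={"control": "GYc", "salinity": "GYs"})
    return out[["GYc", "GYs"]]


def population_means(yields: pd.DataFrame) -> PopulationMeans:
    """Grand means of per-genotype GYc and GYs across all genotypes."""
    means = genotype_mean_yields(yields)
    return PopulationMeans(float(means["GYc"].mean()), float(means["GYs"].mean()))


def compute_sti_row(
    genotype: str, gyc: float, gys: float, means: PopulationMeans
) -> STIRow:
    """All five tolerance indices for one genotype."""
    if gyc <= 0 or gys <= 0:
        raise ValueError("grain yields must be positive")
    denom = 1.0 - means.mean_gys / means.mean_gyc
    if denom == 0:
        raise ValueError(
            "SSI undefined: population means equal under control and salinity"
        )
    ysi = gys / gyc
    return STIRow(
        genotype=genotype,
        gyc=gyc,
        gys=gys,
        ysi=ysi,
        ssi=(1.0 - ysi) / denom,
        sti=(gyc * gys) / means.mean_gyc**2,
        tol=gyc - gys,
        gmp=math.sqrt(gyc * gys),
    )


def sti_table(yields: pd.DataFrame) -> pd.DataFrame:
    """STI feature matrix, one row per genotype (columns GYc..GMP)."""
    means = genotype_mean_yields(yields)
    pop = PopulationMeans(float(means["GYc"].mean()), float(means["GYs"].mean()))
    rows = [
        compute_sti_row(str(g), float(r["GYc"]), float(r["GYs"]), pop)
        for g, r in means.iterrows()
    ]
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in rows],
            "GYc": [r.gyc for r in rows],
            "GYs": [r.gys for r in rows],
            "YSI": [r.ysi for r in rows],
            "SSI": [r.ssi for r in rows],
            "STI": [r.sti for r in rows],
            "TOL": [r.tol for r in rows],
            "GMP": [r.gmp for r in rows],
        }
    ).set_index("genotype")
    return df


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
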