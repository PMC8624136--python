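"""Synthetic salt-tolerance field trial generator.

This module is the package's stand-in for field data: no spectra or
yields from a real trial are distributed, so every downstream stage is
exercised on a generated trial that emulates the study structure —
64 spring-wheat genotypes in three latent tolerance groups, two
treatments (control at ~0.35 dS/m and salinity at 15 dS/m irrigation
water), two years, three replicates.

Generation proceeds in three stages:

1. **Yields.** Each genotype draws a control yield GYc ~ N(mu_g, sd)
   around its group mean and a yield-stability ratio YSI ~ N(ybar_g, sd)
   truncated to (0.40, 0.90); GYs = YSI * GYc.  Plot-level yields add a
   deterministic year offset and Gaussian replicate noise.
2. **Latent canopy traits.** Chlorophyll (c), biomass (b) and water (w)
   proxies in (0, 1] increase affinely with plot yield; salinity applies
   an extra multiplicative reduction (strongest for water status).
3. **Spectra.** Reflectance is a logistic red-edge step between a low
   visible shelf and a NIR plateau whose height rises with biomass,
   declining through the SWIR with water content, minus Gaussian
   absorption wells: pigment wells at 450 and 680 nm (depth ~ c, leaving
   the 550 nm green peak) and water wells at 970, 1170, 1450 and 1950 nm
   (depth ~ w, leaving local maxima near 1640 and 2200 nm).  Smooth
   wavelength-correlated noise is added and the result clipped to
   [0.01, 0.99].

Same seed => bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SpectraSet, SpectrumRecord, WavelengthGrid, build_grid
from .io import KEY_COLS, YIELD_COL

GROUP_NAMES = ("salt-tolerant", "salt-sensitive", "moderately salt-tolerant")


@dataclass(frozen=True)
class SynthConfig:
    """Trial-generator configuration.

    Defaults encode the study conditions: group sizes 25/19/20 with mean
    control yields (6.23, 5.45, 5.18) t/ha and mean yield-stability
    ratios (0.65, 0.63, 0.76).  Within-group spreads are deliberately
    tight (sd 0.12 t/ha, 0.02) so that the planted three-group structure
    is recoverable by clustering — see the methods note for what this
    does and does not emulate.
    """

    n_genotypes: int = 64
    group_sizes: tuple = (25, 19, 20)
    years: int = 2
    replicates: int = 3
    group_gyc_mean: tuple = (6.23, 5.45, 5.18)
    group_gyc_sd: float = 0.12
    group_ysi_mean: tuple = (0.65, 0.63, 0.76)
    group_ysi_sd: float = 0.02
    ysi_bounds: tuple = (0.40, 0.90)
    year_offsets: tuple = (-0.135, 0.135)
    plot_noise_sd: float = 0.20
    # latent trait links: proxy = intercept + slope * (gy - 2)/6 + noise
    trait_intercepts: tuple = (0.25, 0.20, 0.35)   # c, b, w
    trait_slopes: tuple = (0.70, 0.75, 0.55)
    salinity_trait_factors: tuple = (0.92, 0.90, 0.82)  # extra reduction c,b,w
    trait_noise_sd: float = 0.03
    spectral_noise_sd: float = 0.004
    grid_start_nm: int = 350
    grid_end_nm: int = 2500

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_genotypes:
            raise ValueError("group sizes must sum to n_genotypes")
        if min(self.group_sizes) < 1:
            raise ValueError("every group needs at least one genotype")
        for sd in (self.group_gyc_sd, self.group_ysi_sd, self.plot_noise_sd,
                   self.trait_noise_sd, self.spectral_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if len(self.year_offsets) != self.years:
            raise ValueError("need one year offset per year")

    def grid(self) -> WavelengthGrid:
        return build_grid(self.grid_start_nm, self.grid_end_nm, 1)


@dataclass(frozen=True)
class LatentTraits:
    """Canopy property proxies driving the reflectance model."""

    c: float  # chlorophyll / pigment proxy
    b: float  # biomass / leaf-structure proxy
    w: float  # water-status proxy

    def __post_init__(self):
        for v in (self.c, self.b, self.w):
            if not (0.0 < v <= 1.0):
                raise ValueError("traits must lie in (0, 1]")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (exact, seed-reproducible)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def generate_yields(config: SynthConfig, seed: int):
    """Generate the plot-level yield table and planted group labels.

    Returns ``(yields, labels)``: a DataFrame with columns
    ``genotype,treatment,year,rep,gy_t_ha`` and a genotype-indexed Series
    of planted group names.
    """
    rng = np.random.default_rng(seed)
    genotypes = [f"G{i + 1:03d}" for i in range(config.n_genotypes)]
    labels = np.repeat(GROUP_NAMES, config.group_sizes)
    lo, hi = config.ysi_bounds

    gyc = np.concatenate([
        _truncated_normal(rng, m, config.group_gyc_sd, 0.0, np.inf, n)
        for m, n in zip(config.group_gyc_mean, config.group_sizes)
    ])
    ysi = np.concatenate([
        _truncated_normal(rng, m, config.group_ysi_sd, lo, hi, n)
        for m, n in zip(config.group_ysi_mean, config.group_sizes)
    ])
    gys = ysi * gyc

    rows = []
    for gi, geno in enumerate(genotypes):
        for treatment, base in (("control", gyc[gi]), ("salinity", gys[gi])):
            for year in range(1, config.years + 1):
                offset = config.year_offsets[year - 1]
                for rep in range(1, config.replicates + 1):
                    gy = base + offset + rng.normal(0.0, config.plot_noise_sd)
                    rows.append((geno, treatment, year, rep, max(gy, 0.2)))
    yields = pd.DataFrame(rows, columns=KEY_COLS + [YIELD_COL])
    planted = pd.Series(labels, index=pd.Index(genotypes, name="genotype"),
                        name="planted_group")
    return yields, planted


def traits_from_yield(
    gy: float, treatment: str, config: SynthConfig, noise=(0.0, 0.0, 0.0)
) -> LatentTraits:
    """Map a plot yield to canopy trait proxies.

    Affine-increasing in yield, reduced multiplicatively under salinity
    (water status most), clipped to (0, 1].
    """
    if gy <= 0:
        raise ValueError("yield must be positive")
    z = (gy - 2.0) / 6.0
    vals = []
    for i in range(3):
        v = config.trait_intercepts[i] + config.trait_slopes[i] * z + noise[i]
        if treatment == "salinity":
            v *= config.salinity_trait_factors[i]
        vals.append(float(np.clip(v, 1e-3, 1.0)))
    return LatentTraits(*vals)


# Gaussian absorption wells: (centre nm, width nm, base depth, trait depth)
_PIGMENT_WELLS = ((450, 40.0, 0.020, 0.100), (680, 28.0, 0.020, 0.100))
_WATER_WELLS = (
    (970, 35.0, 0.040, 0.100),
    (1170, 45.0, 0.030, 0.080),
    (1450, 55.0, 0.120, 0.280),
    (1950, 75.0, 0.160, 0.340),
)


def _smooth_noise(rng, wavelengths: np.ndarray, sd: float) -> np.ndarray:
    """Wavelength-correlated noise: coarse white knots, cubic interpolation."""
    if sd == 0:
        return np.zeros_like(wavelengths, dtype=float)
    knots = np.arange(wavelengths[0], wavelengths[-1] + 80, 80.0)
    vals = rng.normal(0.0, sd, len(knots))
    from scipy.interpolate import CubicSpline

    return CubicSpline(knots, vals)(wavelengths)


def spectrum_curve(traits: LatentTraits, wavelengths: np.ndarray) -> np.ndarray:
    """Deterministic (noise-free) reflectance curve for given traits."""
    wl = np.asarray(wavelengths, float)
    vis_shelf = 0.12
    nir_height = 0.28 + 0.22 * traits.b
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    base = vis_shelf + (nir_height - vis_shelf) * red_edge
    # SWIR decline: dry-down of the plateau beyond 1300 nm, steeper when wet
    swir = np.clip((wl - 1300.0) / 1200.0, 0.0, 1.0)
    base *= 1.0 - (0.20 + 0.45 * traits.w) * swir
    wells = np.zeros_like(wl)
    for centre, width, d0, d1 in _PIGMENT_WELLS:
        wells += (d0 + d1 * traits.c) * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    for centre, width, d0, d1 in _WATER_WELLS:
        wells += (d0 + d1 * traits.w) * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return np.clip(base - wells, 0.01, 0.99)


def generate_spectrum(
    traits: LatentTraits,
    grid: WavelengthGrid,
    noise_sd: float,
    rng,
    key: tuple = ("G000", "control", 1, 1),
) -> SpectrumRecord:
    """One plot spectrum: deterministic curve plus smooth noise."""
    wl = grid.wavelengths
    refl = spectrum_curve(traits, wl) + _smooth_noise(rng, wl, noise_sd)
    refl = np.clip(refl, 0.01, 0.99)
    genotype, treatment, year, rep = key
    return SpectrumRecord(
        genotype=genotype, treatment=treatment, year=int(year),
        replicate=int(rep), reflectance=refl, grid=grid,
    )


def generate_trial(config: SynthConfig, seed: int):
    """Full factorial trial: (SpectraSet, yield table, planted labels)."""
    yields, planted = generate_yields(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    grid = config.grid()
    records = []
    for _, row in yields.iterrows():
        noise = rng.normal(0.0, config.trait_noise_sd, 3)
        traits = traits_from_yield(row[YIELD_COL], row["treatment"], config, noise)
        records.append(
            generate_spectrum(
                traits, grid, config.spectral_noise_sd, rng,
                key=(row["genotype"], row["treatment"], row["year"], row["rep"]),
            )
        )
    return SpectraSet(grid=grid, records=records), yields, planted
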