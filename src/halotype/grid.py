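"""Wavelength grids and plot-level canopy reflectance spectra.

A field spectroradiometer delivers canopy reflectance (the fraction of
incident radiation reflected, relative to a white reference) on a dense
wavelength grid, conventionally resampled to 1-nm-width bands over
350-2500 nm.  Strong atmospheric water-vapour / CO2 windows carry no
canopy signal and are masked out before any index is computed; here the
default masked windows are 1825-1915 nm and 2470-2500 nm (closed
intervals).

The grid distinguishes *samples* (grid points, ``n_samples``) from
*bands* (1-nm intervals between adjacent samples): the 350-2500 nm grid
at 1 nm has 2151 samples spanning 2150 one-nm bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Atmospheric absorption windows excluded by default, nm (closed intervals).
DEFAULT_MASK_WINDOWS: tuple[tuple[int, int], ...] = ((1825, 1915), (2470, 2500))

VALID_TREATMENTS = ("control", "salinity")


class MissingBandError(KeyError):
    """No usable reflectance sample near a wavelength an index requires."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Integer wavelength grid with an availability mask.

    Parameters
    ----------
    start_nm, end_nm : int
        First and last sampled wavelength, inclusive.
    step_nm : int, default 1
        Grid spacing. The canonical full-range grid uses 1 nm.
    masked : ndarray of bool
        True where the sample is unavailable (atmospheric window).
    """

    start_nm: int
    end_nm: int
    step_nm: int = 1
    masked: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.step_nm < 1:
            raise ValueError(f"step_nm must be >= 1, got {self.step_nm}")
        if self.start_nm >= self.end_nm:
            raise ValueError("start_nm must be < end_nm")
        if (self.end_nm - self.start_nm) % self.step_nm != 0:
            raise ValueError(
                f"span {self.start_nm}-{self.end_nm} nm is not divisible by "
                f"step {self.step_nm} nm"
            )
        if self.masked is None:
            object.__setattr__(self, "masked", np.zeros(self.n_samples, dtype=bool))
        else:
            m = np.asarray(self.masked, dtype=bool)
            if m.shape != (self.n_samples,):
                raise ValueError("mask length does not match sample count")
            object.__setattr__(self, "masked", m)

    @property
    def n_samples(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    @property
    def n_bands(self) -> int:
        """Number of ``step_nm``-width bands between adjacent samples."""
        return (self.end_nm - self.start_nm) // self.step_nm

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, self.step_nm)

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())

    @property
    def n_available(self) -> int:
        return self.n_samples - self.n_masked

    def index_of(self, target_nm: float) -> int:
        """Index of the grid sample nearest ``target_nm`` (ignores mask)."""
        pos = (target_nm - self.start_nm) / self.step_nm
        return int(np.clip(round(pos), 0, self.n_samples - 1))

    def __eq__(self, other):
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.end_nm == other.end_nm
            and self.step_nm == other.step_nm
            and np.array_equal(self.masked, other.masked)
        )

    def __hash__(self):
        return hash((self.start_nm, self.end_nm, self.step_nm, self.masked.tobytes()))


def build_grid(start_nm: int, end_nm: int, step_nm: int = 1) -> WavelengthGrid:
    """Build an unmasked integer wavelength grid.

    ``build_grid(350, 2500, 1)`` gives the canonical full-range grid:
    2151 samples, 2150 one-nm bands.
    """
    return WavelengthGrid(int(start_nm), int(end_nm), int(step_nm))


def apply_mask(grid: WavelengthGrid, windows) -> WavelengthGrid:
    """Mask all samples inside the given closed ``[lo, hi]`` nm windows.

    Windows entirely outside the grid are ignored with a logged warning.
    Idempotent: masking already-masked samples changes nothing.
    """
    masked = grid.masked.copy()
    wl = grid.wavelengths
    for lo, hi in windows:
        if hi < grid.start_nm or lo > grid.end_nm:
            logger.warning(
                "mask window [%s, %s] nm lies outside grid %s-%s nm; ignored",
                lo, hi, grid.start_nm, grid.end_nm,
            )
            continue
        masked |= (wl >= lo) & (wl <= hi)
    return replace(grid, masked=masked)


@dataclass(frozen=True)
class SpectrumRecord:
    """One plot's reflectance spectrum with its experimental keys."""

    genotype: str
    treatment: str
    year: int
    replicate: int
    reflectance: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        if self.treatment not in VALID_TREATMENTS:
            raise ValueError(
                f"treatment must be one of {VALID_TREATMENTS}, got {self.treatment!r}"
            )
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (self.grid.n_samples,):
            raise ValueError(
                f"reflectance length {r.shape} does not match grid sample "
                f"count {self.grid.n_samples}"
            )
        # Percent-scale input (reflectance must be a fraction).
        finite = r[np.isfinite(r)]
        if finite.size and np.nanmax(finite) > 1.5:
            warnings.warn(
                "reflectance values exceed 1.5; assuming percent scale and "
                "dividing by 100",
                stacklevel=2,
            )
            r = r / 100.0
        object.__setattr__(self, "reflectance", r)

    @property
    def key(self) -> tuple:
        return (self.genotype, self.treatment, self.year, self.replicate)


def reflectance_at(
    record: SpectrumRecord, target_nm: float, tolerance_nm: float = 3.0
) -> float:
    """Reflectance at the unmasked sample nearest ``target_nm``.

    Searches within ``tolerance_nm`` of the target (default 3 nm, the
    spectroradiometer's native VIS-NIR sampling interval); ties between
    equally-near neighbours break toward the lower wavelength.

    Raises
    ------
    MissingBandError
        If every sample within tolerance is masked or off-grid.
    """
    grid = record.grid
    wl = grid.wavelengths
    dist = np.abs(wl - target_nm)
    within = (dist <= tolerance_nm) & ~grid.masked
    if not within.any():
        raise MissingBandError(
            f"no unmasked sample within {tolerance_nm} nm of {target_nm} nm"
        )
    cand = np.flatnonzero(within)
    # stable argmin on distance; np.argmin takes the first (lowest wavelength)
    best = cand[np.argmin(dist[cand])]
    return float(record.reflectance[best])


def average_scans(records) -> SpectrumRecord:
    """Element-wise mean of repeated scans of the same plot.

    All records must share grid and (genotype, treatment, year, replicate)
    key; masked samples stay masked.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to average")
    first = records[0]
    for rec in records[1:]:
        if rec.grid != first.grid:
            raise ValueError("records are on different grids")
        if rec.key != first.key:
            raise ValueError(f"key mismatch: {rec.key} vs {first.key}")
    mean = np.mean([rec.reflectance for rec in records], axis=0)
    return SpectrumRecord(
        genotype=first.genotype,
        treatment=first.treatment,
        year=first.year,
        replicate=first.replicate,
        reflectance=mean,
        grid=first.grid,
    )


@dataclass
class SpectraSet:
    """A collection of spectra sharing one grid, keyed uniquely per plot."""

    grid: WavelengthGrid
    records: list

    def __post_init__(self):
        keys = set()
        for rec in self.records:
            if rec.grid != self.grid:
                raise ValueError(f"record {rec.key} is on a different grid")
            if rec.key in keys:
                raise ValueError(f"duplicate plot key {rec.key}")
            keys.add(rec.key)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
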