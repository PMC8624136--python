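"""Spectral reflectance index (SRI) registry and evaluator.

Twenty canopy indices split into two families:

* **vegetation** indices track growth vigour — pigments, photosynthetic
  capacity, green biomass (NDVI variants, chlorophyll indices, EVI,
  MTVI, OSAVI);
* **water** indices track canopy water status and internal leaf
  structure via the weak (970, 1170 nm) and strong (1450, 1950 nm)
  water absorption features (WI, NWI, NDWI, NDMI, NMDI, DMCI, SWSI).

Each index is a declarative :class:`SRIDefinition`: a name, a family, a
list of required wavelengths, and a formula over named reflectances
``R<wavelength>``.  Evaluation resolves each wavelength through
nearest-band lookup on the (possibly masked) grid and propagates any
failure (masked band, division by zero, negative radicand) as an
explicit missing value with a reason — never a silent zero.

Note two registry quirks kept deliberately: BNDVI uses 970 nm as its
NIR term, and WBI pairs 1500 nm with 531 nm; both are retained exactly
as the source registry defines them.  NMDI is the standard normalized
multi-band drought form (R860 - (R1640 - R2130))/(R860 + (R1640 - R2130)).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .grid import MissingBandError, SpectraSet, SpectrumRecord, reflectance_at
from .io import KEY_COLS

logger = logging.getLogger(__name__)

VEGETATION = "vegetation"
WATER = "water"

#: value used in place of an index that could not be computed
MISSING = float("nan")


@dataclass(frozen=True)
class SRIDefinition:
    """A named spectral index: formula string over ``R<nm>`` variables."""

    name: str
    category: str
    wavelengths: tuple
    formula: str

    def evaluate(self, bands: dict) -> float:
        """Evaluate the formula given ``{wavelength: reflectance}``."""
        env = {f"R{w}": bands[w] for w in self.wavelengths}
        env["sqrt"] = _checked_sqrt
        try:
            return float(eval(self.formula, {"__builtins__": {}}, env))  # noqa: S307
        except ZeroDivisionError:
            raise IndexDomainError(f"{self.name}: division by zero") from None


class IndexDomainError(ValueError):
    """The index formula is undefined for these reflectances."""


def _checked_sqrt(x: float) -> float:
    if x <= 0:
        raise IndexDomainError("negative radicand")
    return math.sqrt(x)


def _nd(a: int, b: int) -> str:
    return f"(R{a} - R{b}) / (R{a} + R{b})"


_REGISTRY_SPEC = [
    # --- vegetation ---
    ("NDVI-1", VEGETATION, (750, 705), _nd(750, 705)),
    ("NDVI-2", VEGETATION, (780, 715), _nd(780, 715)),
    ("BNDVI", VEGETATION, (970, 420), _nd(970, 420)),
    ("GNDVI", VEGETATION, (940, 550), _nd(940, 550)),
    ("RNDVI", VEGETATION, (990, 680), _nd(990, 680)),
    ("Chl_green", VEGETATION, (760, 550), "(R760 / R550) - 1"),
    ("Chl_red-edge", VEGETATION, (760, 710), "(R760 / R710) - 1"),
    (
        "EVI",
        VEGETATION,
        (782, 675, 445),
        "2.5 * ((R782 - R675) / (R782 + 6 * R675 - 7.5 * R445 + 1))",
    ),
    (
        "MTVI",
        VEGETATION,
        (800, 550, 670),
        "1.2 * (1.2 * (R800 - R550) - 2.5 * (R670 - R550))",
    ),
    ("OSAVI", VEGETATION, (800, 670), "1.16 * (R800 - R670) / (R800 + R670 + 0.16)"),
    # --- water ---
    ("WI", WATER, (900, 970), "R900 / R970"),
    ("NWI-1", WATER, (970, 880), _nd(970, 880)),
    ("NWI-2", WATER, (970, 900), _nd(970, 900)),
    ("WBI", WATER, (1500, 531), _nd(1500, 531)),
    ("NDWI", WATER, (860, 2270), _nd(860, 2270)),
    ("NDMI", WATER, (2200, 1100), _nd(2200, 1100)),
    ("DMCI", WATER, (2305, 1495), _nd(2305, 1495)),
    (
        "NMDI",
        WATER,
        (860, 1640, 2130),
        "(R860 - (R1640 - R2130)) / (R860 + (R1640 - R2130))",
    ),
    (
        "SWSI-1",
        WATER,
        (803, 681, 1326, 1507),
        "(R803 - R681) / sqrt(R1326 - R1507)",
    ),
    (
        "SWSI-2",
        WATER,
        (803, 681, 905, 972),
        "(R803 - R681) / sqrt(R905 - R972)",
    ),
]

REGISTRY: dict[str, SRIDefinition] = {
    name: SRIDefinition(name, cat, wl, f) for name, cat, wl, f in _REGISTRY_SPEC
}

VEGETATION_INDICES = tuple(d.name for d in REGISTRY.values() if d.category == VEGETATION)
WATER_INDICES = tuple(d.name for d in REGISTRY.values() if d.category == WATER)
ALL_INDICES = VEGETATION_INDICES + WATER_INDICES

assert len(VEGETATION_INDICES) == 10 and len(WATER_INDICES) == 10


@dataclass(frozen=True)
class SRIValue:
    """Computed index value for one plot; NaN value carries a reason."""

    name: str
    key: tuple
    value: float
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.value)


def compute_index(
    definition: SRIDefinition, spectrum: SpectrumRecord, tolerance_nm: float = 3.0
) -> SRIValue:
    """Evaluate one index on one spectrum.

    Missing bands and domain violations yield a NaN value carrying the
    reason; they never propagate as exceptions or silent zeros.
    """
    try:
        bands = {
            w: reflectance_at(spectrum, w, tolerance_nm) for w in definition.wavelengths
        }
        value = definition.evaluate(bands)
    except MissingBandError as exc:
        return SRIValue(definition.name, spectrum.key, MISSING, f"missing band: {exc}")
    except IndexDomainError as exc:
        return SRIValue(definition.name, spectrum.key, MISSING, str(exc))
    return SRIValue(definition.name, spectrum.key, value)


def compute_all(
    spectra: SpectraSet,
    indices=None,
    tolerance_nm: float = 3.0,
) -> pd.DataFrame:
    """Evaluate indices for every plot spectrum.

    Returns a DataFrame with the plot key columns followed by one column
    per index (all 20 by default). Per-index missing counts are logged.
    """
    if len(spectra) == 0:
        raise ValueError("empty spectra set")
    names = list(indices) if indices is not None else list(ALL_INDICES)
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise KeyError(f"unknown indices: {unknown}")
    rows = []
    n_missing = dict.fromkeys(names, 0)
    for rec in spectra:
        row = dict(zip(KEY_COLS, rec.key))
        for name in names:
            sv = compute_index(REGISTRY[name], rec, tolerance_nm)
            if sv.is_missing:
                n_missing[name] += 1
            row[name] = sv.value
        rows.append(row)
    for name, k in n_missing.items():
        if k:
            logger.info("index %s missing for %d of %d plots", name, k, len(spectra))
    return pd.DataFrame(rows)


def export_registry(path) -> None:
    """Write the registry as JSON (name, category, wavelengths, formula)."""
    doc = [
        {
            "name": d.name,
            "category": d.category,
            "wavelengths": list(d.wavelengths),
            "formula": d.formula,
        }
        for d in REGISTRY.values()
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def import_registry(path) -> dict:
    """Read a JSON registry document into SRIDefinition objects."""
    with open(path) as fh:
        doc = json.load(fh)
    return {
        e["name"]: SRIDefinition(
            e["name"], e["category"], tuple(e["wavelengths"]), e["formula"]
        )
        for e in doc
    }
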