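"""Spectral reflectance index registry and evaluator.

The oracle here is an independent set of plain-arithmetic lambdas over a
wavelength->reflectance mapping, written directly from the index
definitions, never sharing code with the registry's formula evaluator.
"""

import math

import numpy as np
import pytest

from halotype import (
    ALL_INDICES,
    REGISTRY,
    SpectraSet,
    VEGETATION_INDICES,
    WATER_INDICES,
    apply_mask,
    compute_all,
    compute_index,
)

# independent direct-arithmetic oracle -----------------------------------
ND = lambda a, b: (a - b) / (a + b)
ORACLE = {
    "NDVI-1": lambda R: ND(R[750], R[705]),
    "NDVI-2": lambda R: ND(R[780], R[715]),
    "BNDVI": lambda R: ND(R[970], R[420]),
    "GNDVI": lambda R: ND(R[940], R[550]),
    "RNDVI": lambda R: ND(R[990], R[680]),
    "Chl_green": lambda R: R[760] / R[550] - 1,
    "Chl_red-edge": lambda R: R[760] / R[710] - 1,
    "EVI": lambda R: 2.5 * (R[782] - R[675]) / (R[782] + 6 * R[675] - 7.5 * R[445] + 1),
    "MTVI": lambda R: 1.2 * (1.2 * (R[800] - R[550]) - 2.5 * (R[670] - R[550])),
    "OSAVI": lambda R: 1.16 * (R[800] - R[670]) / (R[800] + R[670] + 0.16),
    "WI": lambda R: R[900] / R[970],
    "NWI-1": lambda R: ND(R[970], R[880]),
    "NWI-2": lambda R: ND(R[970], R[900]),
    "WBI": lambda R: ND(R[1500], R[531]),
    "NDWI": lambda R: ND(R[860], R[2270]),
    "NDMI": lambda R: ND(R[2200], R[1100]),
    "DMCI": lambda R: ND(R[2305], R[1495]),
    "NMDI": lambda R: (R[860] - (R[1640] - R[2130])) / (R[860] + (R[1640] - R[2130])),
    "SWSI-1": lambda R: (R[803] - R[681]) / math.sqrt(R[1326] - R[1507]),
    "SWSI-2": lambda R: (R[803] - R[681]) / math.sqrt(R[905] - R[972]),
}


def _oracle_value(name, rec):
    R = dict(zip(rec.grid.wavelengths.tolist(), rec.reflectance.tolist()))
    try:
        return ORACLE[name](R)
    except (ValueError, ZeroDivisionError):
        return float("nan")


class TestRegistry:
    def test_ten_vegetation_and_ten_water(self):
        assert len(VEGETATION_INDICES) == 10
        assert len(WATER_INDICES) == 10
        assert len(ALL_INDICES) == 20

    def test_formula_wavelengths_declared(self):
        import re

        for d in REGISTRY.values():
            cited = {int(m) for m in re.findall(r"R(\d+)", d.formula)}
            assert cited == set(d.wavelengths), d.name

    def test_round_trip_json(self, tmp_path):
        from halotype import export_registry, import_registry

        path = tmp_path / "registry.json"
        export_registry(path)
        assert import_registry(path) == REGISTRY


class TestComputeIndex:
    def test_ndvi1_hand_value(self, make_spectrum, full_grid):
        values = np.full(full_grid.n_samples, 0.4)
        values[full_grid.index_of(750)] = 0.50
        values[full_grid.index_of(705)] = 0.25
        sv = compute_index(REGISTRY["NDVI-1"], make_spectrum(values))
        assert sv.value == pytest.approx(1 / 3, abs=1e-4)

    def test_equal_band_identities(self, make_spectrum):
        rec = make_spectrum(0.5)  # constant spectrum
        assert compute_index(REGISTRY["WI"], rec).value == pytest.approx(1.0)
        assert compute_index(REGISTRY["Chl_green"], rec).value == pytest.approx(0.0)
        assert compute_index(REGISTRY["Chl_red-edge"], rec).value == pytest.approx(0.0)
        for name in ("NDVI-1", "GNDVI", "NWI-1", "NDWI"):
            assert compute_index(REGISTRY[name], rec).value == pytest.approx(0.0)

    def test_nmdi_is_one_when_swir_difference_vanishes(self, make_spectrum, full_grid):
        values = np.full(full_grid.n_samples, 0.4)
        values[full_grid.index_of(1640)] = 0.3
        values[full_grid.index_of(2130)] = 0.3
        sv = compute_index(REGISTRY["NMDI"], make_spectrum(values))
        assert sv.value == pytest.approx(1.0)

    def test_swsi_negative_radicand_is_missing(self, make_spectrum, full_grid):
        values = np.full(full_grid.n_samples, 0.4)
        values[full_grid.index_of(1326)] = 0.2
        values[full_grid.index_of(1507)] = 0.3
        sv = compute_index(REGISTRY["SWSI-1"], make_spectrum(values))
        assert sv.is_missing
        assert "radicand" in sv.reason

    def test_masked_band_missing_with_reason(self, full_grid, make_spectrum):
        g = apply_mask(full_grid, [(2100, 2160)])
        rec = make_spectrum(0.4, grid=g)
        sv = compute_index(REGISTRY["NMDI"], rec)
        assert sv.is_missing and "missing band" in sv.reason
        # other indices unaffected by this mask
        assert not compute_index(REGISTRY["NDVI-1"], rec).is_missing


class TestComputeAll:
    def test_twenty_values_per_plot(self, small_trial):
        spectra, _, _ = small_trial
        table = compute_all(spectra)
        assert set(ALL_INDICES) <= set(table.columns)
        assert len(table) == len(spectra)

    def test_registry_matches_oracle_on_random_spectra(self, full_grid, make_spectrum):
        """Registry evaluation equals direct arithmetic to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            rec = make_spectrum(rng.uniform(0.05, 0.95, full_grid.n_samples))
            for name in ALL_INDICES:
                got = compute_index(REGISTRY[name], rec).value
                want = _oracle_value(name, rec)
                if math.isnan(want):
                    assert math.isnan(got), name
                else:
                    assert got == pytest.approx(want, abs=1e-12), name

    def test_empty_set_rejected(self, full_grid):
        with pytest.raises(ValueError):
            compute_all(SpectraSet(grid=full_grid, records=[]))

    def test_unknown_index_rejected(self, small_trial):
        spectra, _, _ = small_trial
        with pytest.raises(KeyError):
            compute_all(spectra, indices=["NOPE"])


class TestInvariants:
    def test_normalized_difference_bounds_and_antisymmetry(
        self, full_grid, make_spectrum
    ):
        rng = np.random.default_rng(3)
        nd_indices = ["NDVI-1", "NDVI-2", "BNDVI", "GNDVI", "RNDVI",
                      "NWI-1", "NWI-2", "WBI", "NDWI", "NDMI", "DMCI"]
        for _ in range(20):
            values = rng.uniform(0.05, 0.95, full_grid.n_samples)
            rec = make_spectrum(values)
            for name in nd_indices:
                v = compute_index(REGISTRY[name], rec).value
                assert -1 < v < 1, name
                a, b = REGISTRY[name].wavelengths
                swapped = values.copy()
                ia, ib = full_grid.index_of(a), full_grid.index_of(b)
                swapped[ia], swapped[ib] = swapped[ib], swapped[ia]
                v2 = compute_index(REGISTRY[name], make_spectrum(swapped)).value
                assert v2 == pytest.approx(-v, abs=1e-12), name

    def test_scale_invariance_of_pure_ratio_indices(self, full_grid, make_spectrum):
        """Multiplying the spectrum by k leaves ratio/ND indices fixed;
        indices with additive constants or square roots must move."""
        rng = np.random.default_rng(5)
        values = rng.uniform(0.05, 0.45, full_grid.n_samples)
        invariant = [n for n in ALL_INDICES
                     if n not in ("EVI", "MTVI", "OSAVI", "SWSI-1", "SWSI-2")]
        rec1, rec2 = make_spectrum(values), make_spectrum(values * 1.7)
        for name in invariant:
            v1 = compute_index(REGISTRY[name], rec1).value
            v2 = compute_index(REGISTRY[name], rec2).value
            assert v2 == pytest.approx(v1, abs=1e-12), name
        for name in ("EVI", "MTVI", "OSAVI"):
            v1 = compute_index(REGISTRY[name], rec1).value
            v2 = compute_index(REGISTRY[name], rec2).value
            assert abs(v2 - v1) > 1e-6, name
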