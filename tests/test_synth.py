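"""Synthetic trial generator: yields, latent traits, spectra."""

import numpy as np
import pandas as pd
import pytest

from halotype import (
    LatentTraits,
    SynthConfig,
    generate_trial,
    generate_yields,
    spectrum_curve,
    traits_from_yield,
)
from halotype.synth import GROUP_NAMES


class TestConfig:
    def test_defaults_encode_study_layout(self):
        cfg = SynthConfig()
        assert cfg.n_genotypes == 64 and cfg.group_sizes == (25, 19, 20)
        assert cfg.years == 2 and cfg.replicates == 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_genotypes=10, group_sizes=(5, 4, 2))
        with pytest.raises(ValueError):
            SynthConfig(plot_noise_sd=-0.1)
        with pytest.raises(ValueError):
            SynthConfig(years=3)  # needs a third year offset


class TestYields:
    def test_same_seed_identical_different_seed_not(self):
        cfg = SynthConfig()
        y1, p1 = generate_yields(cfg, 5)
        y2, p2 = generate_yields(cfg, 5)
        y3, _ = generate_yields(cfg, 6)
        pd.testing.assert_frame_equal(y1, y2)
        pd.testing.assert_series_equal(p1, p2)
        assert not y1["gy_t_ha"].equals(y3["gy_t_ha"])

    def test_zero_sd_gives_exact_group_means(self):
        cfg = SynthConfig(group_gyc_sd=0.0, group_ysi_sd=0.0,
                          plot_noise_sd=0.0, year_offsets=(0.0, 0.0))
        yields, planted = generate_yields(cfg, 0)
        control = yields[yields["treatment"] == "control"]
        means = control.groupby("genotype")["gy_t_ha"].mean()
        for grp, mu in zip(GROUP_NAMES, cfg.group_gyc_mean):
            genos = planted.index[planted == grp]
            assert np.allclose(means[genos], mu)

    def test_large_sample_group_means_converge(self):
        """Law of large numbers: scaled-up trial reproduces the planted
        group mean control yields within 0.05 t/ha."""
        cfg = SynthConfig(n_genotypes=6400, group_sizes=(2500, 1900, 2000),
                          years=1, replicates=1, year_offsets=(0.0,))
        yields, planted = generate_yields(cfg, 1)
        control = yields[yields["treatment"] == "control"].set_index("genotype")
        for grp, mu in zip(GROUP_NAMES, cfg.group_gyc_mean):
            genos = planted.index[planted == grp]
            assert abs(control.loc[genos, "gy_t_ha"].mean() - mu) < 0.05

    def test_all_yields_positive_and_ysi_bounded(self):
        cfg = SynthConfig()
        yields, planted = generate_yields(cfg, 2)
        assert (yields["gy_t_ha"] > 0).all()
        wide = (yields.groupby(["genotype", "treatment"])["gy_t_ha"].mean()
                .unstack("treatment"))
        ysi = wide["salinity"] / wide["control"]
        assert ysi.between(0.3, 1.0).all()  # noise widens the planted band a little

    def test_structure_is_full_factorial(self):
        yields, _ = generate_yields(SynthConfig(), 3)
        assert len(yields) == 64 * 2 * 2 * 3
        counts = yields.groupby(["genotype", "treatment", "year", "rep"]).size()
        assert (counts == 1).all()


class TestTraits:
    def test_monotone_in_yield(self):
        cfg = SynthConfig()
        lo = traits_from_yield(3.0, "control", cfg)
        hi = traits_from_yield(6.5, "control", cfg)
        assert hi.c >= lo.c and hi.b >= lo.b and hi.w >= lo.w

    def test_salinity_reduces_water_at_equal_yield(self):
        cfg = SynthConfig()
        ctrl = traits_from_yield(5.0, "control", cfg)
        salt = traits_from_yield(5.0, "salinity", cfg)
        assert salt.w <= ctrl.w and salt.c <= ctrl.c

    def test_closed_form_without_noise(self):
        cfg = SynthConfig()
        t = traits_from_yield(5.0, "control", cfg)
        z = (5.0 - 2.0) / 6.0
        assert t.c == pytest.approx(cfg.trait_intercepts[0] + cfg.trait_slopes[0] * z)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            traits_from_yield(-1.0, "control", SynthConfig())
        with pytest.raises(ValueError):
            LatentTraits(0.0, 0.5, 0.5)


class TestSpectra:
    def test_chlorophyll_deepens_red_absorption(self, full_grid):
        wl = full_grid.wavelengths
        lush = spectrum_curve(LatentTraits(1.0, 0.6, 0.6), wl)
        pale = spectrum_curve(LatentTraits(0.2, 0.6, 0.6), wl)
        i680, i550 = full_grid.index_of(680), full_grid.index_of(550)
        assert lush[i680] < pale[i680]
        assert lush[i550] > lush[i680]  # green peak above red valley
        assert pale[i550] > pale[i680]

    def test_water_wells_deepen_with_w(self, full_grid):
        wl = full_grid.wavelengths
        wet = spectrum_curve(LatentTraits(0.6, 0.6, 0.9), wl)
        dry = spectrum_curve(LatentTraits(0.6, 0.6, 0.2), wl)

        def well_depth(curve, centre, flank=60):
            i = full_grid.index_of(centre)
            j = full_grid.index_of(centre - flank)
            return curve[j] - curve[i]

        for centre in (970, 1170):
            assert well_depth(wet, centre) > well_depth(dry, centre)
        # local maxima near 1640 and 2200 between the strong wells
        for curve in (wet, dry):
            for centre in (1640, 2200):
                i = full_grid.index_of(centre)
                assert curve[i] > curve[full_grid.index_of(centre - 150)]
                assert curve[i] > curve[full_grid.index_of(centre + 150)]

    def test_curves_deterministic_and_bounded(self, full_grid):
        wl = full_grid.wavelengths
        c1 = spectrum_curve(LatentTraits(0.5, 0.5, 0.5), wl)
        c2 = spectrum_curve(LatentTraits(0.5, 0.5, 0.5), wl)
        assert np.array_equal(c1, c2)
        assert (c1 >= 0.01).all() and (c1 <= 0.99).all()


class TestTrial:
    def test_reflectance_bounds_and_determinism(self, small_trial):
        spectra, yields, planted = small_trial
        for rec in spectra:
            assert (rec.reflectance >= 0.01).all()
            assert (rec.reflectance <= 0.99).all()
        cfg = SynthConfig(n_genotypes=6, group_sizes=(2, 2, 2))
        spectra2, yields2, _ = generate_trial(cfg, 11)
        pd.testing.assert_frame_equal(yields, yields2)
        assert np.array_equal(spectra.records[0].reflectance,
                              spectra2.records[0].reflectance)

    def test_group_reflectance_orderings(self):
        """Tolerant group: lowest visible, highest near-infrared mean
        reflectance; sensitive group lowest NIR under salinity."""
        spectra, _, planted = generate_trial(SynthConfig(), 0)
        wl = spectra.grid.wavelengths
        vis = (wl >= 400) & (wl <= 700)
        nir = (wl >= 750) & (wl <= 1300)
        rows = [
            (planted[rec.genotype], rec.treatment,
             rec.reflectance[vis].mean(), rec.reflectance[nir].mean())
            for rec in spectra
        ]
        df = pd.DataFrame(rows, columns=["group", "treatment", "vis", "nir"])
        means = df.groupby(["treatment", "group"]).mean()
        for trt in ("control", "salinity"):
            sub = means.loc[trt]
            assert sub["vis"].idxmin() == "salt-tolerant"
            assert sub["nir"].idxmax() == "salt-tolerant"
        assert means.loc["salinity", "nir"].idxmin() == "salt-sensitive"

    def test_smoke_all_downstream_stages(self, small_trial, tmp_path):
        from halotype import RunConfig, run_pipeline

        cfg = RunConfig(
            synth=SynthConfig(n_genotypes=6, group_sizes=(2, 2, 2)),
            seed=11, out_dir=str(tmp_path / "out"),
        )
        bundle = run_pipeline(cfg)
        assert len(bundle["sti_table"]) == 6
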