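import numpy as np
import pytest

from halotype import (
    DEFAULT_MASK_WINDOWS,
    SpectrumRecord,
    SynthConfig,
    apply_mask,
    build_grid,
    generate_trial,
)


@pytest.fixture(scope="session")
def full_grid():
    return build_grid(350, 2500, 1)


@pytest.fixture(scope="session")
def masked_grid(full_grid):
    return apply_mask(full_grid, DEFAULT_MASK_WINDOWS)


@pytest.fixture
def make_spectrum(full_grid):
    """Factory: SpectrumRecord from an array or a constant."""

    def _make(values, grid=None, **key):
        grid = grid or full_grid
        if np.isscalar(values):
            values = np.full(grid.n_samples, float(values))
        defaults = dict(genotype="G001", treatment="control", year=1, replicate=1)
        defaults.update(key)
        return SpectrumRecord(reflectance=np.asarray(values, float), grid=grid,
                              **defaults)

    return _make


@pytest.fixture(scope="session")
def small_trial():
    """Tiny but complete trial: 6 genotypes, 2 per tolerance group."""
    cfg = SynthConfig(n_genotypes=6, group_sizes=(2, 2, 2))
    return generate_trial(cfg, seed=11)
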