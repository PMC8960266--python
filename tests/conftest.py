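import numpy as np
import pytest

from ramanld import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ch_grid():
    """A short grid covering the C-H stretching region only."""
    return np.arange(2700.0, 3101.0, 1.0)


@pytest.fixture
def small_cohort():
    """A 2x2 cohort on a short grid: quick input for grouped operations."""
    design = sd.CohortDesign(
        cell_lines=("MDA-MB-231",),
        methionine_levels=(1.0, 20.0),
        insulin_levels=(1.0, 2.0),
        multipliers={("MDA-MB-231", 20.0, 2.0): {2850.0: 1.3}},
        cells_per_group=2,
        spectra_per_cell=3,
        grid=np.arange(2700.0, 3101.0, 1.0),
        noise_sd=0.02,
        seed=7,
    )
    sset, truth = sd.generate_spectrum_cohort(design)
    return sset, truth, design
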