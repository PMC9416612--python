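import numpy as np
import pytest

from serumnmr import (
    SimulationConfig,
    load_default_library,
    load_default_presence_table,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def presence():
    return load_default_presence_table()


@pytest.fixture(scope="session")
def small_cohort(library):
    """8 vs 6 subjects in triplicate on a 4096-point grid, all nuisances on."""
    config = SimulationConfig(
        n_subjects_per_class=(8, 6), grid=(0.0, 10.0, 4096), seed=11
    )
    return simulate_cohort(library, config)


@pytest.fixture(scope="session")
def clean_cohort(library):
    """Nuisance-free cohort: no noise, jitter, dilution or baseline."""
    config = SimulationConfig(
        n_subjects_per_class=(5, 5),
        grid=(0.0, 10.0, 4096),
        noise_sd=0.0,
        baseline_slope_range=(0.0, 0.0),
        baseline_offset_range=(0.0, 0.0),
        shift_jitter_sd=0.0,
            global_shift_sd=0.0,
        dilution_log_sd=0.0,
        concentration_cv=0.1,
        include_water_hump=False,
        include_lipid_humps=False,
        seed=5,
    )
    return simulate_cohort(library, config)


@pytest.fixture(scope="session")
def planted_marker_matrix():
    """Class-labelled matrix with 10 planted discriminatory columns.

    60 samples x 500 variables of unit Gaussian noise; the first class gets
    a +1.5 mean shift on 10 known columns.
    """
    rng = np.random.default_rng(42)
    n, p = 60, 500
    X = rng.normal(size=(n, p))
    y = np.repeat([1.0, 0.0], n // 2)
    marker_cols = np.arange(25, 500, 50)[:10]
    X[y == 1][:, marker_cols] += 0.0  # fancy-index copy guard (no-op)
    X[np.ix_(y == 1, marker_cols)] += 1.5
    labels = np.where(y == 1, "Schizophrenia", "Control")
    return X, y, labels, marker_cols
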