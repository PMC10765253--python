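import numpy as np
import pandas as pd
import pytest

from falff.spectral import TimeSeriesGrid

TR = 0.735
N_TP = 490


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def grid_factory():
    """Build a TimeSeriesGrid from rows (defaults: study TR and length)."""

    def make(values, tr=TR):
        return TimeSeriesGrid(np.atleast_2d(np.asarray(values, float)), tr)

    return make


@pytest.fixture
def cohort_factory():
    """A confounded two-group participant table with given sizes."""

    def make(n_treated, n_control, seed):
        from falff.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            seed=seed, n_hypertensive=n_treated, n_normotensive=n_control
        )
        table, _ = simulate_cohort(cfg)
        return table

    return make
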