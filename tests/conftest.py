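import pandas as pd
import pytest

import pollenflow as pf
from pollenflow.field_model import Dataset


def make_dataset(rows, k_grains=400.0):
    """rows: list of (experiment_id, grid_id, distance, fb_width, cp_grains)."""
    df = pd.DataFrame(
        rows,
        columns=["experiment_id", "grid_id", "distance_m", "fb_width_m", "cp_grains"],
    )
    return Dataset(df=df, k_grains=k_grains)


@pytest.fixture
def toy_dataset():
    """Six cobs over three grids, two experiments, mixed FB widths."""
    return make_dataset(
        [
            ("A", "g1", 0.75, 0.0, 120),
            ("A", "g1", 0.75, 0.0, 95),
            ("A", "g2", 3.0, 0.0, 20),
            ("A", "g2", 3.0, 0.0, 0),
            ("B", "g1", 7.5, 7.5, 60),
            ("B", "g2", 9.0, 7.5, 12),
        ]
    )


@pytest.fixture(scope="session")
def small_suite():
    """Scaled-down three-experiment suite (every 2nd row, 4 cobs/grid)."""
    parts = pf.paper_scale_suite(seed=11, row_stride=2, cobs_per_grid=4)
    return parts[0].concat(parts[1]).concat(parts[2])


@pytest.fixture(scope="session")
def small_suite_zexpob_fit(small_suite):
    return pf.fit_mle(small_suite, "ZExpoB", seed=11, n_starts=3)


@pytest.fixture(scope="session")
def small_suite_zexpob_chain(small_suite):
    return pf.run_mcmc(small_suite, "ZExpoB", settings=pf.McmcSettings(seed=11))
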