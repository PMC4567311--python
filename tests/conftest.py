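import warnings

import pandas as pd
import pytest

from gallstand import pipeline
from gallstand.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One synthetic study at the default (field-design) configuration."""
    return simulate_dataset(seed=0)


@pytest.fixture(scope="session")
def plot_result(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_plot_level(dataset, seed=0)


@pytest.fixture(scope="session")
def nbh_result(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_neighborhood_level(dataset, seed=0)


@pytest.fixture
def toy_trees():
    """Five mapped trees in one 30 m plot: three chestnuts, an oak, a hophornbeam."""
    return pd.DataFrame(
        dict(
            tree_id=["t1", "t2", "t3", "t4", "t5"],
            plot_id="A",
            species=["CS", "CS", "CS", "QC", "OC"],
            x=[15.0, 18.0, 25.0, 13.0, 16.0],
            y=[15.0, 15.0, 25.0, 17.0, 12.0],
            dbh=[30.0, 20.0, 25.0, 22.0, 18.0],
            height=[18.0, 12.0, 14.0, 16.0, 10.0],
            crown_area=[20.0, 10.0, 12.0, 15.0, 8.0],
            clump_id=pd.NA,
        )
    )
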