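import numpy as np
import pandas as pd
import pytest

import canopygp as cg


@pytest.fixture(scope="session")
def small_config() -> cg.SimulationConfig:
    """A fast 40-accession campaign at coarse raster resolution."""
    return cg.SimulationConfig(
        seed=11,
        n_accessions=40,
        n_genotyped=36,
        n_markers=300,
        n_qtl=40,
        resolution_m=0.05,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config) -> cg.SimulatedExperiment:
    return cg.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_height_table(small_experiment) -> pd.DataFrame:
    """Combined UAV + ruler height table for the small campaign."""
    uav = cg.extract_plot_heights(
        small_experiment.canopy, small_experiment.ground, small_experiment.layout
    )
    return pd.concat([uav, small_experiment.ruler], ignore_index=True)


@pytest.fixture()
def flat_raster():
    """A 60x40 flat raster at 0.1 m resolution, origin at (0, 6)."""
    return cg.Raster(np.full((60, 40), 5.0), resolution=0.1, origin=(0.0, 6.0))
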