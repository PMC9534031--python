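"""Shared fixtures: a small but fully-featured simulated trial."""

import warnings

import pandas as pd
import pytest

import cloverqg as cq
from cloverqg.traits import derive_trait_table, to_wide


def small_config(seed: int = 7) -> cq.SimulationConfig:
    """24 families x 2 replicates x 4 plants/quadrant, all three arms.

    Family variances are large relative to the residual so that the family
    component is Wald-significant even at this size, letting the selection
    stages of the pipeline run.
    """
    return cq.SimulationConfig(
        n_families=24,
        n_replicates=2,
        plants_per_quadrant=4,
        containers_per_replicate=6,
        treatment_means={
            cq.TA1: {"shoot_dm": 11.4, "root_dm": 5.03},
            cq.NPLUS: {"shoot_dm": 25.1, "root_dm": 9.0},
        },
        components={
            cq.TA1: {
                "shoot_dm": cq.VarianceSet(13.5, 0.5, 1.0, 0.2, 0.2, 6.0),
                "root_dm": cq.VarianceSet(2.2, 0.1, 0.3, 0.05, 0.05, 1.2),
            },
            cq.NPLUS: {
                "shoot_dm": cq.VarianceSet(23.3, 1.0, 2.0, 0.4, 0.4, 12.0),
                "root_dm": cq.VarianceSet(3.4, 0.15, 0.4, 0.08, 0.08, 2.0),
            },
        },
        genetic_correlation=0.8,
        negative_control=cq.NegativeControl(n_containers=1),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_trial() -> tuple[pd.DataFrame, dict]:
    return cq.simulate_trial(small_config())


@pytest.fixture(scope="session")
def small_plot(small_trial) -> pd.DataFrame:
    plants, _ = small_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return derive_trait_table(plants)


@pytest.fixture(scope="session")
def wide_ta1(small_plot) -> pd.DataFrame:
    return to_wide(small_plot, cq.TA1)


@pytest.fixture()
def oneway_toy() -> pd.DataFrame:
    """Balanced one-way layout with closed-form REML: groups {1,3} and {5,7}."""
    return pd.DataFrame({"family": [1, 1, 2, 2], "response": [1.0, 3.0, 5.0, 7.0]})
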