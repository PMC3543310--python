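import numpy as np
import pytest

from gcsteroid.bayes_calibration import LikelihoodEvaluator, metropolis_hastings
from gcsteroid.model_core import default_hierarchy, load_parameters, load_preset, load_priors
from gcsteroid.sim_invitro import InVitroSystem
from gcsteroid.synthetic_data import generate_collection, truth_from_map


@pytest.fixture(scope="session")
def table2_params():
    return load_parameters("table2_defaults")


@pytest.fixture(scope="session")
def map_params():
    return load_parameters("table4_map")


@pytest.fixture(scope="session")
def map_preset():
    return load_preset("table4_map")


@pytest.fixture(scope="session")
def flux_system():
    return InVitroSystem.from_config(load_preset("flux_assay"))


@pytest.fixture(scope="session")
def priors():
    return load_priors()


@pytest.fixture(scope="session")
def hier10():
    return default_hierarchy(10)


@pytest.fixture(scope="session")
def synthetic_collection(table2_params, map_preset):
    """Ten-study synthetic calibration collection generated at the
    calibrated (MAP) truth with the hierarchical noise model."""
    truth = truth_from_map(map_preset)
    data, record = generate_collection(truth, table2_params, seed=42)
    return data, record, truth


@pytest.fixture(scope="session")
def calibration_run(synthetic_collection, table2_params, priors, hier10):
    """Scaled-down triplicate-chain calibration (3 x 5000) on the synthetic
    collection; shared by the convergence and recovery tests."""
    data, record, _truth = synthetic_collection
    ev = LikelihoodEvaluator(data, table2_params)
    chains = metropolis_hastings(data, priors, hier10, n_iter=5000,
                                 n_chains=3, seeds=[101, 102, 103],
                                 params=table2_params, evaluator=ev)
    return chains, record


@pytest.fixture(scope="session")
def prior_only_run(priors, hier10):
    """MH sampling of the bare prior (no data): used for prior-recovery."""
    return metropolis_hastings(None, priors, hier10, n_iter=4000,
                               n_chains=3, seeds=[5, 6, 7])
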