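import warnings

import numpy as np
import pytest

import coregflow as cf
from coregflow.simulate import simulate_reference

warnings.filterwarnings("ignore", message="only .* samples")


def run_study(seed: int, decouple: bool = False, **sim_kw):
    """One full study at the default conditions: simulate reference + query,
    infer on the compendium, integrate evidence, score influence on the
    query, and test for differential influence."""
    cfg = cf.SimulationConfig(seed=seed, decouple_mrna=decouple, **sim_kw)
    query, evidence, truth = cf.simulate_dataset(cfg)
    compendium = simulate_reference(cfg)
    catalog = cf.RegulatorCatalog(frozenset(truth.true_activity.index))
    candidates = cf.infer_candidate_programs(compendium, catalog)
    network = cf.integrate_evidence(candidates, evidence)
    influence = cf.influence_matrix(query, network)
    dirs = cf.identify_dirs(influence, query.condition_of, "baseline", "stimulated")
    return {
        "config": cfg,
        "query": query,
        "evidence": evidence,
        "truth": truth,
        "network": network,
        "influence": influence,
        "dirs": dirs,
    }


N_SEEDS = 20


@pytest.fixture(scope="session")
def default_bundle():
    """Twenty independent studies at the default planted-node conditions."""
    return [run_study(seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def decoupled_bundle():
    """Twenty studies with regulator mRNA decoupled from activity."""
    return [run_study(seed, decouple=True) for seed in range(N_SEEDS)]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
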