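import pytest

from nemabar import PipelineConfig, SimulationConfig, run_pipeline
from nemabar.datasets import load_copse_annotations, load_copse_profiles
from nemabar.rotu import cluster_isolates
from nemabar.synthetic import simulate_all, simulate_reference_set


@pytest.fixture(scope="session")
def copse_profiles():
    return load_copse_profiles()


@pytest.fixture(scope="session")
def copse_rotus(copse_profiles):
    rotus = cluster_isolates(copse_profiles)
    ann = load_copse_annotations()
    order_map = dict(zip(ann.sample_id, ann.order))
    feed_map = dict(zip(ann.sample_id, ann.feeding_code))
    for r in rotus:
        r.order = order_map[r.members[0]]
        r.feeding_code = feed_map[r.members[0]]
    return rotus


@pytest.fixture(scope="session")
def sim_default():
    """One simulated study at the default (survey-scale) conditions."""
    config = SimulationConfig(seed=11)
    references, tables, truth = simulate_all(config)
    return config, references, tables, truth


@pytest.fixture(scope="session")
def references_small():
    config = SimulationConfig(n_orders=4, species_per_order=3, seed=7)
    references, truth = simulate_reference_set(config)
    return config, references, truth


@pytest.fixture(scope="session")
def pipeline_bundle():
    """Full synthetic pipeline at survey scale with 100 bootstrap replicates."""
    sim = SimulationConfig(seed=11)
    cfg = PipelineConfig(seed=11, bootstrap=100)
    return sim, cfg, run_pipeline(sim, cfg)
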