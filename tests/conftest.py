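import pytest
from hypothesis import HealthCheck, settings

import rnaihts as r

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

NULL_TRUTH = r.TruthModel(p_null=1.0, p_pos=0.0, p_neg=0.0, p_viability=0.0, p_rl_artifact=0.0)
CLEAN_ERRORS = r.ErrorModel(edge_plate_prob=0.0, dropout_prob=0.0)


@pytest.fixture(scope="session")
def small_null_screen():
    """4-plate triplicate screen with no planted effects or artefacts."""
    cfg = r.SimulationConfig(n_plates=4, replicates=3, seed=42)
    dataset, truth, graph = r.simulate_screen(cfg, NULL_TRUTH, CLEAN_ERRORS)
    return dataset, truth, graph


@pytest.fixture(scope="session")
def small_null_scored(small_null_screen):
    dataset, _, _ = small_null_screen
    return r.score_screen(dataset, None, r.ScoringConfig())


@pytest.fixture(scope="session")
def full_null_screen():
    """Genome-scale pure-null screen: 53 plates, triplicate, no artefacts."""
    cfg = r.SimulationConfig(n_plates=53, replicates=3, seed=404)
    dataset, truth, _ = r.simulate_screen(cfg, NULL_TRUTH, CLEAN_ERRORS)
    return dataset, truth


@pytest.fixture(scope="session")
def full_null_scored(full_null_screen):
    dataset, _ = full_null_screen
    return r.score_screen(dataset, None, r.ScoringConfig())


@pytest.fixture(scope="session")
def planted_screen():
    """6-plate screen with planted regulators, viability and RL-artifact genes."""
    cfg = r.SimulationConfig(n_plates=6, replicates=3, seed=7)
    truth_model = r.TruthModel(
        p_null=0.93, p_pos=0.02, p_neg=0.02, p_viability=0.01, p_rl_artifact=0.02
    )
    dataset, truth, graph = r.simulate_screen(cfg, truth_model, CLEAN_ERRORS)
    return dataset, truth, graph


@pytest.fixture(scope="session")
def planted_scored(planted_screen):
    dataset, _, _ = planted_screen
    return r.score_screen(dataset, None, r.ScoringConfig())
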