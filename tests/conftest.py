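import pytest

from ddiscreen import (ModelConfig, ScenarioConfig, generate_scenario,
                       load_templates, run_study)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study, run once per session: shipped
    scenario, reduced-width nine-layer model, 20 epochs."""
    return run_study(ScenarioConfig(), model_cfg=ModelConfig.desk())


@pytest.fixture(scope="session")
def small_scenario():
    """A cheap scenario for structural (non-learning) checks."""
    return generate_scenario(ScenarioConfig(
        n_drugs=60, n_patients=50, n_food_compounds=20, n_food_sources=15,
        seed=7))


@pytest.fixture(scope="session")
def templates():
    return load_templates()


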