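import pytest

from ffpm import (
    SimulationConfig,
    default_archetypes,
    ff_plate_layout,
    generate_dataset,
)


@pytest.fixture(scope="session")
def layout():
    return ff_plate_layout()


@pytest.fixture(scope="session")
def sim_default(layout):
    """One default planted-effect simulation (5 reps, full grid), with truth."""
    config = SimulationConfig(
        archetypes=default_archetypes(layout, seed=11), seed=11
    )
    dataset, truth = generate_dataset(config, layout)
    return dataset, truth


@pytest.fixture(scope="session")
def sim_one_rep(layout):
    config = SimulationConfig(
        archetypes=default_archetypes(layout, seed=3), n_rep=1, seed=3
    )
    dataset, _ = generate_dataset(config, layout)
    return dataset
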