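import numpy as np
import pytest

from glomfen import FenestrationParams, network, simulate
from glomfen.modelio import default_glucose, default_model


@pytest.fixture(scope="session")
def spec():
    return default_model()


@pytest.fixture(scope="session")
def schedule():
    sched, _ = default_glucose()
    return sched


@pytest.fixture(scope="session")
def glucose_stats():
    _, stats = default_glucose()
    return stats


@pytest.fixture(scope="session")
def params():
    return FenestrationParams()


@pytest.fixture(scope="session")
def disease_traj(spec, schedule):
    """Disease-variant network trajectory on the mean schedule, weeks 2-20."""
    return simulate(spec, schedule, t_span=(336.0, 3360.0), grid_h=6.0)


@pytest.fixture(scope="session")
def healthy_traj(spec, schedule):
    return simulate(
        spec.with_variant("healthy"), schedule, t_span=(336.0, 3360.0), grid_h=6.0
    )


@pytest.fixture(scope="session")
def noiseless_obs(spec, schedule, params):
    from glomfen import make_observations

    return make_observations(
        params, schedule=schedule, spec=spec, sd_density=0.0, sd_width=0.0, seed=0
    )


def toy_chain_spec():
    """3-node toy network GLU -> A -> B with an inhibiting side edge."""
    species = [
        network.SpeciesSpec(id="GLU"),
        network.SpeciesSpec(id="A"),
        network.SpeciesSpec(id="B", ymax=0.8),
    ]
    reactions = [
        network.ReactionSpec(id=1, inputs=(), target="GLU"),
        network.ReactionSpec(id=2, inputs=(("GLU", "activating"),), target="A", W=0.9),
        network.ReactionSpec(
            id=3,
            inputs=(("A", "activating"), ("GLU", "inhibiting")),
            target="B",
            n=2.0,
            ec50=0.4,
        ),
        network.ReactionSpec(id=4, inputs=(("GLU", "activating"),), target="B", W=0.5),
    ]
    return network.NetworkSpec(species=species, reactions=reactions)
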