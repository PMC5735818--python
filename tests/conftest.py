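import numpy as np
import pytest

import follisim as fs


@pytest.fixture(scope="session")
def scenario_models():
    return {
        name: fs.build_scenario(fs.ScenarioSpec.for_scenario(name))
        for name in ("SF", "DF", "DF_miRNA")
    }


@pytest.fixture(scope="session")
def scenario_runs(scenario_models):
    settings = fs.SimulationSettings()
    return {name: fs.simulate(m, settings) for name, m in scenario_models.items()}


@pytest.fixture(scope="session")
def readouts(scenario_models):
    return fs.default_readouts(scenario_models["SF"])


@pytest.fixture(scope="session")
def comparison(scenario_runs, readouts):
    return fs.compare_scenarios(scenario_runs, readouts)


def binding_model(kf=1.0, kr=0.5, a0=1.0, b0=1.0, ab0=0.0):
    """A + B <-> AB, the minimal reversible test network."""
    return fs.NetworkModel(
        species=[
            fs.SpeciesDef(id="A", initial_amount=a0),
            fs.SpeciesDef(id="B", initial_amount=b0),
            fs.SpeciesDef(id="AB", initial_amount=ab0),
        ],
        reactions=[
            fs.ReactionDef(id="bind", reactants=[("A", 1), ("B", 1)],
                           products=[("AB", 1)], kf=kf, kr=kr),
        ],
        name="binding",
    )


def chain_model(k1=1.0, k2=2.0, a0=1.0):
    """A -> B -> C irreversible chain with closed-form B peak."""
    return fs.NetworkModel(
        species=[
            fs.SpeciesDef(id="A", initial_amount=a0),
            fs.SpeciesDef(id="B"),
            fs.SpeciesDef(id="C"),
        ],
        reactions=[
            fs.ReactionDef(id="r1", reactants=[("A", 1)], products=[("B", 1)], kf=k1),
            fs.ReactionDef(id="r2", reactants=[("B", 1)], products=[("C", 1)], kf=k2),
        ],
        name="chain",
    )
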