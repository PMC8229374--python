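import numpy as np
import pytest

from cgemkit.cancer_scores import DEFAULT_ALIASES
from cgemkit.model_io import MetabolicModel, Reaction, protect_reactions
from cgemkit.omics_mapping import ReactionActivity
from cgemkit.synthetic_data import ToyModelSpec, make_toy_model


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(ToyModelSpec())


@pytest.fixture(scope="session")
def protected(toy_model):
    return protect_reactions(toy_model, DEFAULT_ALIASES.protected_set())


def make_chain(lb1=0.0, ub1=10.0):
    """EX_a -> r1 -> r2 -> EX_b linear chain with bounds [0, 10]."""
    return MetabolicModel(
        model_id="chain",
        metabolites=["a", "b", "c"],
        reactions=[
            Reaction("EX_a", -10.0, 0.0, {"a": -1.0}),
            Reaction("r1", lb1, ub1, {"a": -1.0, "b": 1.0}),
            Reaction("r2", 0.0, 10.0, {"b": -1.0, "c": 1.0}),
            Reaction("EX_b", 0.0, 10.0, {"c": -1.0}),
        ],
        objective_reaction="r2",
    )


@pytest.fixture
def chain_model():
    return make_chain()


def activity(values, sample_id="s"):
    return ReactionActivity(sample_id=sample_id, values=values)


def uniform_activity(model, value=1.0, sample_id="s"):
    return ReactionActivity(
        sample_id=sample_id,
        values={r.reaction_id: value for r in model.reactions},
    )
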