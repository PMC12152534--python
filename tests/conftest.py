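import numpy as np
import pytest

from fluxsig.model import MetabolicModel, Metabolite, Reaction
from fluxsig.synthetic import (
    SyntheticExpressionConfig,
    ToyModelConfig,
    generate_synthetic_expression,
    generate_toy_model,
)


def make_box_model(sides, model_id="box"):
    """One source/sink pair per side: the net flux of pair i is uniform on
    [0, sides[i]], so the polytope is an axis-aligned box with known
    marginal moments."""
    mets, rxns = [], []
    for i, L in enumerate(sides):
        mets.append(Metabolite(f"m{i}"))
        rxns.append(Reaction(f"SRC{i}", {f"m{i}": 1.0}, 0.0, float(L)))
        rxns.append(Reaction(f"SNK{i}", {f"m{i}": -1.0}, 0.0, 10.0 * float(L)))
    return MetabolicModel(metabolites=mets, reactions=rxns, id=model_id)


@pytest.fixture(scope="session")
def toy():
    """A fixed toy model + ground truth shared across the suite."""
    return generate_toy_model(ToyModelConfig(seed=11))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_expression(toy_model):
    return generate_synthetic_expression(
        toy_model, SyntheticExpressionConfig(seed=12)
    )


@pytest.fixture(scope="session")
def toy_samples(toy_model):
    """5000 stored solutions of the (unconstrained) toy model."""
    from fluxsig.sampler import sample_model

    return sample_model(
        toy_model, total_iterations=300_000, thinning=60, seed=13, phase="pool"
    )
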