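import numpy as np
import pytest

from boolpert.likelihood_hmm import ExperimentDesign, PerturbationDataset
from boolpert.model_core import NodeRoster, SignalingNetwork
from boolpert.synthetic_data import (
    GeneratorSpec,
    default_emission,
    default_shortterm_design,
    example_truth_network,
    generate_dataset,
)


@pytest.fixture(scope="session")
def truth_net() -> SignalingNetwork:
    return example_truth_network()


@pytest.fixture(scope="session")
def short_design():
    return default_shortterm_design()


@pytest.fixture(scope="session")
def planted_data(truth_net, short_design):
    """One short-term dataset drawn from the planted network (seed 1)."""
    spec = GeneratorSpec(truth_net, short_design,
                         default_emission(len(truth_net.roster.proteins)),
                         seed=1)
    data, assignment = generate_dataset(spec)
    return data, assignment


@pytest.fixture
def tiny_roster() -> NodeRoster:
    names = ("A", "B", "C", "S")
    roles = {"A": "protein", "B": "protein", "C": "protein", "S": "stimulus"}
    return NodeRoster(names, roles)


@pytest.fixture
def cascade_net(tiny_roster) -> SignalingNetwork:
    """S -> A -> B -> C."""
    return SignalingNetwork.from_edges(
        tiny_roster, [("S", "A", 1), ("A", "B", 1), ("B", "C", 1)]
    )


def make_dataset(roster, conditions, timepoints, values, replicates=None):
    """Small dataset helper: values shaped (P, C, T, R)."""
    values = np.asarray(values, dtype=float)
    reps = replicates or (values.shape[3],) * len(conditions)
    design = ExperimentDesign(tuple(conditions), tuple(timepoints), "min",
                              tuple(reps))
    return PerturbationDataset(roster, design, values)


def random_roster(rng, n_proteins, n_stimuli=1, n_drugs=1) -> NodeRoster:
    names = tuple(
        [f"p{i}" for i in range(n_proteins)]
        + [f"s{i}" for i in range(n_stimuli)]
        + [f"d{i}" for i in range(n_drugs)]
    )
    roles = {}
    for n in names:
        roles[n] = {"p": "protein", "s": "stimulus", "d": "drug"}[n[0]]
    return NodeRoster(names, roles)
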