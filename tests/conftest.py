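"""Shared fixtures: small alphabets, models and simulated alignments.

Everything is generated programmatically and seeded; session-scoped
fixtures cache the more expensive simulations.
"""

import numpy as np
import pytest

from streptophylo import substmodels as sm
from streptophylo.alignment import Alignment, Alphabet
from streptophylo.inference import random_binary_tree
from streptophylo.simulate import SimulationConfig, simulate_alignment
from streptophylo.trees import parse_newick


@pytest.fixture(scope="session")
def toy_alphabet():
    return Alphabet("ABCD", "toy4")


@pytest.fixture(scope="session")
def toy_mixture(toy_alphabet):
    """A 2-class, 2-gamma-category mixture on a 4-letter alphabet."""
    e = sm.ExchangeabilityMatrix(np.array(
        [[0, 1, 2, 0.5], [1, 0, 1.5, 0.7], [2, 1.5, 0, 1.2], [0.5, 0.7, 1.2, 0]]))
    f1 = sm.FrequencyProfile(np.array([0.1, 0.2, 0.3, 0.4]))
    f2 = sm.FrequencyProfile(np.array([0.4, 0.3, 0.2, 0.1]))
    return sm.SubstitutionMixtureModel(
        e, [(f1, 0.6), (f2, 0.4)], sm.discrete_gamma(0.7, 2), toy_alphabet)


@pytest.fixture(scope="session")
def lg_model():
    return sm.make_model("lg", alpha=0.8)


@pytest.fixture(scope="session")
def five_taxon_tree():
    return parse_newick("((A:0.3,B:0.1):0.2,(C:0.5,D:0.05):0.15,E:0.4);")


@pytest.fixture(scope="session")
def toy_alignment(toy_alphabet):
    return Alignment({"A": "ABCADDBC", "B": "BBAADCBC", "C": "CDCABBCA",
                      "D": "ADCDBBCA", "E": "ABDACBCA"}, toy_alphabet)


@pytest.fixture(scope="session")
def six_taxon_sim(lg_model):
    """Strong-signal simulation on a fixed 6-taxon tree (2000 sites)."""
    tree = parse_newick(
        "((A:0.2,B:0.15):0.08,(C:0.25,(D:0.1,E:0.12):0.07):0.05,F:0.3);")
    aln, _ = simulate_alignment(
        SimulationConfig(tree=tree, model=lg_model, sites=2000, seed=42))
    return tree, aln


def random_trees(n_leaves, count, seed=0, mean_length=0.2):
    rng = np.random.default_rng(seed)
    return [random_binary_tree([f"t{i}" for i in range(n_leaves)], rng,
                               mean_length) for _ in range(count)]
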