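import numpy as np
import pytest
from scipy.stats import chisquare

from protnet import InteractionNetwork, make_fixture_network


@pytest.fixture
def triangle():
    return InteractionNetwork.from_named_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def dimer_net():
    """Two species, one interaction: the minimal binding system."""
    return InteractionNetwork(["A", "B"], [(0, 1)])


@pytest.fixture
def clique_ring():
    """A clique-rich 24-species interactome (4 cliques of 6 in a ring)."""
    return make_fixture_network("ring_of_cliques", 4, clique_size=6)


def chi2_class_test(counts: dict, probs: dict, min_expected: float = 5.0):
    """Chi-square of observed class counts against exact class probabilities.

    Classes whose expected count falls below ``min_expected`` are pooled
    into one cell (standard validity rule); an impossible class (probability
    zero) with a nonzero observation fails outright.
    """
    n = sum(counts.values())
    classes = sorted(set(probs) | set(counts))
    for c in classes:
        if probs.get(c, 0.0) == 0.0:
            assert counts.get(c, 0) == 0, f"impossible class {c} observed"
    obs = np.array([counts.get(c, 0) for c in classes], dtype=float)
    exp = np.array([probs.get(c, 0.0) * n for c in classes])
    keep = exp >= min_expected
    obs = np.append(obs[keep], obs[~keep].sum())
    exp = np.append(exp[keep], exp[~keep].sum())
    if exp[-1] == 0:
        obs, exp = obs[:-1], exp[:-1]
    stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
    return p
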