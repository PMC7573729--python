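"""Shared fixtures and small independent simulation helpers for the tests."""

from __future__ import annotations

import numpy as np
import pytest

from dupdiv import DistanceMatrix, SubstitutionModel, simulate_family_tree
from dupdiv.models import RateMixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_additive_matrix(n_tips: int, seed: int) -> tuple[DistanceMatrix, object]:
    """A distance matrix that is exactly additive on a random Yule tree."""
    from dupdiv import cophenetic

    tree = simulate_family_tree(n_tips, 1.0, seed)
    return cophenetic(tree), tree


def simulate_alignment_on_tree(
    tree,
    n_sites: int,
    model: SubstitutionModel,
    mixture: RateMixture,
    seed: int,
    continuous_gamma_alpha: float | None = None,
):
    """Site-wise simulation of sequences down a tree under P(t) draws.

    Independent of the package's Gillespie codon simulator: ancestral states
    are drawn from pi and each branch applies the transition matrix directly,
    which makes this a suitable oracle-side generator.  Per-site rates come
    from the discrete mixture, or from a continuous gamma when
    ``continuous_gamma_alpha`` is given.
    """
    rs = np.random.default_rng(seed)
    states = model.states
    pi = model.pi
    n_states = len(states)
    if continuous_gamma_alpha is not None:
        rates = rs.gamma(continuous_gamma_alpha, 1.0 / continuous_gamma_alpha, n_sites)
    else:
        cats = rs.integers(0, len(mixture.rates), n_sites)
        rates = np.asarray(mixture.rates)[cats]
    if mixture.p_inv > 0:
        rates = np.where(rs.random(n_sites) < mixture.p_inv, 0.0, rates)
    root = rs.choice(n_states, size=n_sites, p=pi)
    seqs = {}

    def evolve(parent_states, t):
        child = parent_states.copy()
        for rate in np.unique(rates):
            idx = np.flatnonzero(rates == rate)
            if rate == 0 or len(idx) == 0:
                continue
            p = model.transition_matrix(t * rate)
            cum = p.cumsum(axis=1)
            u = rs.random(len(idx))
            child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
        return child

    node_states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_states[id(node)] = root
        else:
            node_states[id(node)] = evolve(
                node_states[id(node.parent_node)], node.edge.length
            )
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(
                states[k] for k in node_states[id(node)]
            )
    return seqs


def simulate_pair(
    t: float,
    n_sites: int,
    model: SubstitutionModel,
    mixture: RateMixture,
    seed: int,
    continuous_gamma_alpha: float | None = None,
) -> tuple[str, str]:
    """Two sequences separated by total distance t (oracle-side generator)."""
    rs = np.random.default_rng(seed)
    n_states = len(model.states)
    if continuous_gamma_alpha is not None:
        rates = rs.gamma(continuous_gamma_alpha, 1.0 / continuous_gamma_alpha, n_sites)
    else:
        cats = rs.integers(0, len(mixture.rates), n_sites)
        rates = np.asarray(mixture.rates)[cats]
    if mixture.p_inv > 0:
        rates = np.where(rs.random(n_sites) < mixture.p_inv, 0.0, rates)
    x = rs.choice(n_states, size=n_sites, p=model.pi)
    y = x.copy()
    for rate in np.unique(rates):
        idx = np.flatnonzero(rates == rate)
        if rate == 0 or len(idx) == 0:
            continue
        p = model.transition_matrix(t * rate)
        cum = p.cumsum(axis=1)
        u = rs.random(len(idx))
        y[idx] = (u[:, None] > cum[x[idx]]).sum(axis=1)
    a = "".join(model.states[k] for k in x)
    b = "".join(model.states[k] for k in y)
    return a, b


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The 3-class synthetic dataset used by the pipeline tests."""
    from dupdiv.simulate import generate_multiclass_fixture

    out = tmp_path_factory.mktemp("fixture")
    cfg_path = generate_multiclass_fixture(out, 20240101)
    return cfg_path
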