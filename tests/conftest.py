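import itertools

import numpy as np
import pytest

from flagmot import ctmc, simulate


@pytest.fixture(scope="session")
def yule50():
    return simulate.simulate_yule_tree(50, seed=11)


@pytest.fixture(scope="session")
def small_tree_and_trait():
    tree = simulate.simulate_yule_tree(5, seed=9)
    sim = simulate.simulate_binary_trait(tree, 0.3, 0.7, seed=1)
    return sim.tree_arrays, sim.tip_dict()


def enumeration_log_likelihood(arrays, tip_states, model, root_prior=None):
    """Brute-force likelihood: sum over every state assignment of internal
    nodes (and of missing tips), multiplying the per-edge transition
    probabilities and the root prior. Exponential in tree size — for oracle
    use on tiny trees only."""
    Q = ctmc.build_rate_matrix(model)
    k = model.n_states
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    state_idx = {s: i for i, s in enumerate(model.states)}
    fixed = {}
    free = []
    for label, node in arrays.tip_index.items():
        state = tip_states[label]
        if state == "-":
            free.append(node)
        else:
            fixed[node] = state_idx[state]
    for node in range(arrays.n_nodes):
        if node not in arrays.tip_index.values() and node not in fixed:
            if node not in free:
                free.append(node)
    edge_P = {n: ctmc.transition_probabilities(Q, arrays.lengths[n])
              for n in range(arrays.n_nodes) if arrays.parent[n] >= 0}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(fixed)
        prob = root_prior[st[arrays.root]]
        for n, P in edge_P.items():
            prob *= P[st[arrays.parent[n]], st[n]]
        total += prob
    return np.log(total) if total > 0 else -np.inf
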