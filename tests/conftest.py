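import numpy as np
import pytest

from phylodisp.ctmc import GeoModelParams, build_rate_matrix
from phylodisp.geodata import GeographicData, read_tip_areas
from phylodisp.tree import Tree, read_newick_tree


@pytest.fixture
def four_tip_tree() -> Tree:
    return read_newick_tree("((A:1.0,B:1.0):0.5,(C:0.8,D:0.8):0.7);")


@pytest.fixture
def four_tip_data(four_tip_tree) -> GeographicData:
    table = "taxon,area\nA,x\nB,y\nC,x\nD,y\n"
    return read_tip_areas(table, four_tip_tree)


@pytest.fixture
def two_state_Q():
    """Symmetric k=2 rate chain with unit rate: Q = [[-1,1],[1,-1]]."""
    params = GeoModelParams(symmetric=True, r=np.ones(1), delta=np.ones(1, dtype=int), mu=1.0)
    return build_rate_matrix(params, 2)


def enumerate_log_likelihood(tree, data, Q, root_freqs=None):
    """Brute-force likelihood: sum over every assignment of internal-node
    states, multiplying exp(Qt) transition probabilities along branches.
    Independent oracle for the pruning recursion."""
    import itertools

    from phylodisp.ctmc import transition_probabilities

    k = data.k
    if root_freqs is None:
        root_freqs = np.full(k, 1.0 / k)
    tip_state = data.tip_state_vector(tree)
    internal = [i for i in range(tree.n_nodes) if tree.children(i)]
    P = {n: transition_probabilities(Q, float(tree.branch_length[n]))
         for n in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in range(tree.n_nodes):
            if tip_state[n] >= 0:
                state[n] = int(tip_state[n])
        p = root_freqs[state[tree.root]]
        for n in range(tree.n_nodes):
            if n == tree.root:
                continue
            p *= P[n][state[tree.parent[n]], state[n]]
        total += p
    return np.log(total) if total > 0 else float("-inf")
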