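import numpy as np
import pytest

from locusmix.graph import parse_graph

TWO_POP_MIG = """
ROOT R
BRANCH R s 0.02
BRANCH s P1 0.01
BRANCH R t 0.015
BRANCH t P2 0.005
MIG m1 s t
LEAF P1 pop1
LEAF P2 pop2
"""

TWO_POP_TREE = """
ROOT R
BRANCH R P1 0.03
BRANCH R P2 0.02
LEAF P1 pop1
LEAF P2 pop2
"""


@pytest.fixture
def two_pop_mig():
    return parse_graph(TWO_POP_MIG)


@pytest.fixture
def two_pop_tree():
    return parse_graph(TWO_POP_TREE)


@pytest.fixture
def four_pop_tip():
    from locusmix.simulate import four_population_graph

    return four_population_graph("tip")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_small_graph(rng, max_pops=4, max_migs=2):
    """Random small admixture graph for property tests.

    Builds a random bifurcating tree, then attaches migration edges
    between mid-branch nodes of distinct lineages where acyclicity can
    hold, retrying until validation passes.
    """
    from locusmix.graph import Branch, MigrationEdge, PopulationGraph, GraphError

    while True:
        M = int(rng.integers(2, max_pops + 1))
        leaves = [f"P{i}" for i in range(M)]
        nodes = list(leaves)
        branches = []
        counter = [0]

        def new_internal():
            counter[0] += 1
            return f"n{counter[0]}"

        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            parent = new_internal()
            branches.append(Branch(parent, a, float(rng.uniform(0.005, 0.05))))
            branches.append(Branch(parent, b, float(rng.uniform(0.005, 0.05))))
            nodes = [n for n in nodes if n not in (a, b)] + [parent]
        root = nodes[0]
        # split random branches to host migration endpoints
        migs = []
        n_mig = int(rng.integers(0, max_migs + 1))
        for mi in range(n_mig):
            if len(branches) < 2:
                break
            bi, bj = rng.choice(len(branches), size=2, replace=False)
            src_branch, tgt_branch = branches[int(bi)], branches[int(bj)]
            s_node, t_node = f"ms{mi}", f"mt{mi}"
            for node, br in ((s_node, src_branch), (t_node, tgt_branch)):
                k = branches.index(br)
                half = br.length / 2
                branches[k] = Branch(br.parent, node, half)
                branches.insert(k + 1, Branch(node, br.child, half))
            migs.append(MigrationEdge(f"m{mi}", s_node, t_node))
        g = PopulationGraph(root, branches, migs, {lf: lf.lower() for lf in leaves})
        try:
            g.validate()
            return g
        except GraphError:
            continue
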