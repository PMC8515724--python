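import numpy as np
import pytest

from teendrop.bn import BayesNet, Cpt, validate_dag


def make_net(nodes, edges, p1_tables):
    """Build a binary BayesNet from {node: flat list of P(node=1 | parent cfg)}
    with parents in lexicographic order, rows row-major over parent states."""
    dag = validate_dag(nodes, edges)
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        p1 = np.asarray(p1_tables[node], dtype=float).reshape(
            tuple(2 for _ in parents))
        cpts[node] = Cpt(node=node, parents=parents,
                         table=np.stack([1 - p1, p1], axis=-1))
    return BayesNet(dag=dag, cpts=cpts)


def random_net(rng, max_nodes=8, max_parents=3):
    """A random binary network: random DAG + CPT entries in [0.05, 0.95]."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"X{i}" for i in range(n)]
    order = list(rng.permutation(names))
    edges = []
    for j, child in enumerate(order):
        candidates = order[:j]
        rng.shuffle(candidates)
        n_par = min(len(candidates), int(rng.integers(0, max_parents + 1)))
        for parent in candidates[:n_par]:
            edges.append((parent, child))
    p1 = {node: rng.uniform(0.05, 0.95, size=2 ** sum(1 for e in edges if e[1] == node))
          for node in names}
    return make_net(names, edges, p1)


@pytest.fixture
def chain_net():
    """A -> B with P(A=1)=.5, P(B=1|A=0)=.1, P(B=1|A=1)=.9."""
    return make_net(["A", "B"], [("A", "B")], {"A": [0.5], "B": [0.1, 0.9]})


@pytest.fixture
def fork_collider_net():
    """The 4-node example graph X -> Y -> W <- Z with hand CPTs."""
    return make_net(
        ["X", "Z", "Y", "W"], [("X", "Y"), ("Y", "W"), ("Z", "W")],
        {"X": [0.6], "Z": [0.3], "Y": [0.2, 0.9],
         # parents of W sorted: (Y, Z); rows (Y=0,Z=0),(0,1),(1,0),(1,1)
         "W": [0.1, 0.4, 0.7, 0.8]})


@pytest.fixture
def confounded_net():
    """Z -> X, Z -> Y, X -> Y: the classic single-confounder triangle."""
    return make_net(
        ["Z", "X", "Y"], [("Z", "X"), ("Z", "Y"), ("X", "Y")],
        {"Z": [0.5], "X": [0.2, 0.8],
         # parents of Y sorted: (X, Z); rows (X=0,Z=0),(0,1),(1,0),(1,1)
         "Y": [0.1, 0.5, 0.6, 0.9]})
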