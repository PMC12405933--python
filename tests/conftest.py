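import numpy as np
import pandas as pd
import pytest

from exacbn.data import DiscreteData
from exacbn.graphs import cpdag_of_dag
from exacbn.synthetic import make_ground_truth_network, sample_cohort


@pytest.fixture(scope="session")
def core9():
    return make_ground_truth_network("core9")


@pytest.fixture(scope="session")
def core9_cpdag(core9):
    return cpdag_of_dag(core9.dag())


@pytest.fixture(scope="session")
def cohort_20k(core9):
    return sample_cohort(core9, 20000, seed=11)


@pytest.fixture(scope="session")
def bands_20k(core9, cohort_20k):
    return DiscreteData.from_dataframe(core9.discretize(cohort_20k))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_discrete_net(rng, max_nodes=8, max_levels=3):
    """A random DAG with random CPTs, as plain dicts (test helper)."""
    from exacbn.bayesnet import DiscreteBayesNet
    from exacbn.graphs import NetworkStructure

    n = int(rng.integers(3, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    arcs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                arcs.add((names[i], names[j]))
    dag = NetworkStructure(tuple(names), arcs)
    levels = {m: [str(k) for k in range(int(rng.integers(2, max_levels + 1)))]
              for m in names}
    cpts = {}
    for m in names:
        ps = tuple(sorted(dag.parents(m)))
        shape = tuple(len(levels[p]) for p in ps) + (len(levels[m]),)
        raw = rng.random(shape) + 0.05
        cpts[m] = raw / raw.sum(axis=-1, keepdims=True)
    return DiscreteBayesNet(dag, levels, cpts)


def enumerate_posterior(net, query, evidence):
    """Brute-force posterior by summing the full joint (oracle)."""
    from itertools import product

    from exacbn.bayesnet import joint_probability

    nodes = list(net.dag.nodes)
    cards = [len(net.levels[m]) for m in nodes]
    ev_idx = {k: net.levels[k].index(str(v)) if isinstance(v, str)
              else int(v) for k, v in evidence.items()}
    out = np.zeros(len(net.levels[query]))
    for combo in product(*(range(c) for c in cards)):
        a = dict(zip(nodes, combo))
        if any(a[k] != v for k, v in ev_idx.items()):
            continue
        out[a[query]] += joint_probability(net, a)
    return out / out.sum()
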