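import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from moanet import SimulationConfig, generate_interactome, make_benchmark_scenario

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_network() -> nx.Graph:
    return generate_interactome(60, 2, seed=1)


@pytest.fixture(scope="session")
def benchmark():
    return make_benchmark_scenario()


@pytest.fixture()
def path_network() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    g.add_node("D")
    return g


def random_scenario(seed: int):
    """Random small network + gene sets + fold changes for oracle checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 31))
    nodes = [f"N{i}" for i in range(n)]
    p = rng.uniform(0.08, 0.35)
    edges = {
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    k = int(rng.integers(1, max(2, n // 2)))
    genes = set(rng.choice(nodes, size=k, replace=False))
    n_fc = int(rng.integers(0, n))
    fc_genes = rng.choice(nodes, size=n_fc, replace=False) if n_fc else []
    fc = {
        gene: float(rng.choice([-1, 1]) * rng.uniform(1.0, 2.5)) for gene in fc_genes
    }
    evid_genes = rng.choice(nodes, size=int(rng.integers(0, n)), replace=False)
    evidence = {gene: int(rng.integers(1, 6)) for gene in evid_genes}
    return g, nodes, edges, genes, fc, evidence


@pytest.fixture()
def null_trial_config():
    return SimulationConfig(n_subjects_per_arm=100, planted_effects={}, seed=0)


def trial_frame(rows):
    return pd.DataFrame(rows, columns=["subject", "arm", "visit_week", "biomarker", "value"])
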