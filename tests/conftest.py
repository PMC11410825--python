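import numpy as np
import pandas as pd
import pytest

from ppifuse.go_features import GoDag
from ppifuse.physchem import ScaleTable
from ppifuse.synthetic import SynthConfig, generate_pairs, generate_universe

AA = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def scale2() -> ScaleTable:
    """Synthetic 20 x 2 scale table so correctness never depends on bundled values."""
    values = pd.DataFrame(
        {"alpha": np.arange(20, dtype=float), "beta": np.arange(20, dtype=float) ** 2 / 10.0},
        index=AA,
    )
    return ScaleTable(values)


@pytest.fixture
def diamond_dag() -> GoDag:
    """R -> {B, C} -> D diamond plus a spare leaf E under C."""
    edges = [("B", "R"), ("C", "R"), ("D", "B"), ("D", "C"), ("E", "C")]
    ns = {t: "biological_process" for t in "RBCDE"}
    return GoDag(edges, ns)


@pytest.fixture
def star_dag() -> GoDag:
    edges = [("B", "R"), ("C", "R"), ("D", "R")]
    return GoDag(edges, {t: "biological_process" for t in "RBCD"})


@pytest.fixture(scope="session")
def small_universe():
    """A small but fully structured synthetic dataset shared across tests."""
    config = SynthConfig(
        n_proteins=40, n_pairs=120, dag_size=24, terms_per_protein=(4, 8),
        length_range=(40, 80), seed=11,
    )
    universe = generate_universe(config)
    pairs = generate_pairs(universe, config)
    return universe, pairs


def random_dag(rng: np.random.Generator, n_nodes: int) -> GoDag:
    """Random single-namespace rooted DAG: each node attaches to 1-2 existing nodes."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        n_parents = 1 + int(rng.random() < 0.4 and i > 1)
        parents = rng.choice(i, size=n_parents, replace=False)
        edges.extend((names[i], names[int(p)]) for p in parents)
    return GoDag(edges, {n: "biological_process" for n in names})


def brute_force_lca(dag: GoDag, terms) -> str:
    """Independent oracle: intersect ancestor-or-self sets, pick max depth, min id."""
    common = None
    for t in terms:
        anc = {t}
        frontier = [t]
        while frontier:
            node = frontier.pop()
            for p in dag.parents(node):
                if p not in anc:
                    anc.add(p)
                    frontier.append(p)
        common = anc if common is None else common & anc
    if not common:
        return dag.root(dag.namespace(next(iter(terms))))
    return sorted(common, key=lambda n: (-dag.depth(n), n))[0]
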