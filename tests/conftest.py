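"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riskbn.bayesnet import CPT, DAG, BayesNet
from riskbn.codebook import default_codebook


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture()
def two_node_net():
    """A -> D with P(A=1)=0.3, P(D=1|A=0)=0.2, P(D=1|A=1)=0.8."""
    dag = DAG(["A", "D"], [("A", "D")])
    return BayesNet(
        dag,
        {"A": (0, 1), "D": (0, 1)},
        {
            "A": CPT("A", (), [[0.7, 0.3]]),
            "D": CPT("D", ("A",), [[0.8, 0.2], [0.2, 0.8]]),
        },
    )


def random_binary_net(rng: np.random.Generator, n_nodes: int) -> BayesNet:
    """Random DAG (edge prob 0.4 over an ordered triangle) with random CPTs."""
    nodes = [f"X{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.4
    ]
    dag = DAG(nodes, edges)
    states = {n: (0, 1) for n in nodes}
    cpts = {}
    for n in nodes:
        q = 2 ** len(dag.parents(n))
        p1 = rng.uniform(0.05, 0.95, size=q)
        cpts[n] = CPT(n, dag.parents(n), np.column_stack([1 - p1, p1]))
    return BayesNet(dag, states, cpts)


def strong_signal_net() -> BayesNet:
    """Fixed 8-node ground truth, all conditional probabilities in {0.1, 0.9}.

    Structure mixes chains, a branch and two colliders (OR-gates) so its
    equivalence class is informative.
    """
    nodes = list("ABCDEFGH")
    edges = [
        ("A", "C"), ("B", "C"), ("C", "D"), ("D", "F"), ("E", "F"),
        ("F", "G"), ("C", "H"),
    ]
    dag = DAG(nodes, edges)
    lo, hi = 0.1, 0.9
    cpts = {}
    for n in nodes:
        ps = dag.parents(n)
        if not ps:
            cpts[n] = CPT(n, (), [[1 - lo, lo]])
        elif len(ps) == 1:
            cpts[n] = CPT(n, ps, [[1 - lo, lo], [1 - hi, hi]])
        else:
            rows = [
                [1 - (hi if any(cfg) else lo), hi if any(cfg) else lo]
                for cfg in itertools.product((0, 1), repeat=len(ps))
            ]
            cpts[n] = CPT(n, ps, rows)
    return BayesNet(dag, {n: (0, 1) for n in nodes}, cpts)


def enumerate_all_dags(nodes: list[str]):
    """Every DAG on the given nodes (oracle-side acyclicity via DFS)."""
    pairs = [(u, v) for u in nodes for v in nodes if u < v]
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                edges.append((u, v))
            elif c == 2:
                edges.append((v, u))
        adj = {n: [] for n in nodes}
        for u, v in edges:
            adj[u].append(v)

        def has_cycle(start):
            stack = [(start, iter(adj[start]))]
            on_path = {start}
            visited = {start}
            while stack:
                node, it = stack[-1]
                for child in it:
                    if child in on_path:
                        return True
                    if child not in visited:
                        visited.add(child)
                        on_path.add(child)
                        stack.append((child, iter(adj[child])))
                        break
                else:
                    on_path.discard(node)
                    stack.pop()
            return False

        if not any(has_cycle(n) for n in nodes):
            yield edges


def chain_data(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A -> B -> C with strong links."""
    a = (rng.random(n) < 0.5).astype(int)
    b = np.where(a == 1, rng.random(n) < 0.9, rng.random(n) < 0.1).astype(int)
    c = np.where(b == 1, rng.random(n) < 0.9, rng.random(n) < 0.1).astype(int)
    return pd.DataFrame({"A": a, "B": b, "C": c})


def collider_data(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A -> C <- B (OR gate) with independent balanced parents."""
    a = (rng.random(n) < 0.5).astype(int)
    b = (rng.random(n) < 0.5).astype(int)
    c = np.where(
        (a | b) == 1, rng.random(n) < 0.85, rng.random(n) < 0.1
    ).astype(int)
    return pd.DataFrame({"A": a, "B": b, "C": c})
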