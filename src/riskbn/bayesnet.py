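"""Discrete Bayesian-network containers: DAG, CPT and BayesNet.

A BayesNet is a directed acyclic graph over named nodes, each node carrying
a finite state vocabulary and a conditional probability table (CPT) over
its parents.  The joint distribution factorizes as the product of the CPTs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class CyclicGraphError(ValueError):
    """Raised when a graph expected to be acyclic contains a cycle."""


class InvalidNetError(ValueError):
    """Raised for structurally inconsistent network objects."""


@dataclass(frozen=True)
class DAG:
    """Immutable directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes, edges=()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(
            self, "edges", frozenset((str(u), str(v)) for u, v in edges)
        )
        if len(set(self.nodes)) != len(self.nodes):
            raise InvalidNetError("duplicate node names")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise InvalidNetError(f"self-loop {u}->{v}")
            if u not in node_set or v not in node_set:
                raise InvalidNetError(f"edge {u}->{v} uses undeclared node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CyclicGraphError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in declared node order (deterministic)."""
        return tuple(u for u in self.nodes if (u, node) in self.edges)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if (node, v) in self.edges)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def with_edge(self, u: str, v: str) -> "DAG":
        return DAG(self.nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "DAG":
        return DAG(self.nodes, self.edges - {(u, v)})

    def reversed_edge(self, u: str, v: str) -> "DAG":
        return DAG(self.nodes, (self.edges - {(u, v)}) | {(v, u)})


@dataclass
class CPT:
    """Conditional probability table of one node given its parents.

    ``table`` has shape ``(prod(parent cards), n_states)``; rows are indexed
    by the parent configuration in row-major order over ``parents`` (first
    parent varies slowest).  ``counts`` holds the per-row training sample
    size (0 for configurations never observed, which receive uniform rows).
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise InvalidNetError(f"{self.node}: CPT must be 2-D")
        if np.any(self.table < -1e-12) or np.any(self.table > 1 + 1e-12):
            raise InvalidNetError(f"{self.node}: probabilities outside [0,1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidNetError(f"{self.node}: CPT rows must sum to 1")
        if self.counts is None:
            self.counts = np.zeros(self.table.shape[0])
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_states(self) -> int:
        return self.table.shape[1]


@dataclass
class BayesNet:
    """A DAG plus one CPT per node and per-node state vocabularies.

    ``states`` maps node -> ordered tuple of state values (ints or strings);
    CPT columns follow that order.
    """

    dag: DAG
    states: dict[str, tuple]
    cpts: dict[str, CPT] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.states or len(self.states[node]) < 1:
                raise InvalidNetError(f"missing states for node {node}")
        for node, cpt in self.cpts.items():
            self._check_cpt(node, cpt)

    def _check_cpt(self, node: str, cpt: CPT) -> None:
        if node not in set(self.dag.nodes):
            raise InvalidNetError(f"CPT for undeclared node {node}")
        if tuple(cpt.parents) != self.dag.parents(node):
            raise InvalidNetError(
                f"{node}: CPT parents {cpt.parents} != DAG parents "
                f"{self.dag.parents(node)}"
            )
        if cpt.n_states != len(self.states[node]):
            raise InvalidNetError(
                f"{node}: CPT has {cpt.n_states} columns for "
                f"{len(self.states[node])} states"
            )
        expected_rows = int(
            np.prod([len(self.states[p]) for p in cpt.parents])
        ) if cpt.parents else 1
        if cpt.table.shape[0] != expected_rows:
            raise InvalidNetError(
                f"{node}: CPT has {cpt.table.shape[0]} rows, expected "
                f"{expected_rows}"
            )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def card(self, node: str) -> int:
        return len(self.states[node])

    def state_index(self, node: str, state) -> int:
        try:
            return self.states[node].index(state)
        except ValueError:
            raise InvalidNetError(
                f"{node}: unknown state {state!r}; declared "
                f"{self.states[node]}"
            ) from None

    def parent_configurations(self, node: str):
        """Iterate parent-state tuples in CPT row order."""
        parents = self.dag.parents(node)
        return itertools.product(*(self.states[p] for p in parents))

    def cpt_row_index(self, node: str, parent_states: dict) -> int:
        parents = self.dag.parents(node)
        idx = 0
        for p in parents:
            idx = idx * self.card(p) + self.state_index(p, parent_states[p])
        return idx

    def __eq__(self, other) -> bool:
        if not isinstance(other, BayesNet):
            return NotImplemented
        if self.dag != other.dag or self.states != other.states:
            return False
        if set(self.cpts) != set(other.cpts):
            return False
        return all(
            np.array_equal(self.cpts[n].table, other.cpts[n].table)
            for n in self.cpts
        )
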