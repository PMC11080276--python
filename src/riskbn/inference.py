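"""Exact inference by variable elimination.

Factors are dense arrays over small discrete scopes; elimination follows a
min-degree order over the moralized evidence-reduced graph.  The networks
here have at most ~18 nodes, so exact sum-product is comfortably fast and
no junction tree is needed.

Predictive queries condition the disease node on observed risk factors;
diagnostic queries clamp the disease node and read the posterior shift of
every other node.  Records with unobserved variables are handled by plain
marginalization — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesnet import BayesNet


class ImpossibleEvidenceError(ValueError):
    """The supplied evidence has probability zero under the network."""


@dataclass
class Factor:
    """Nonnegative table over the joint states of its scope."""

    scope: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.scope):
            raise ValueError("factor dimensionality mismatch")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("factor entries must be finite and nonnegative")


def _cpt_factor(net: BayesNet, node: str) -> Factor:
    cpt = net.cpts[node]
    scope = cpt.parents + (node,)
    shape = tuple(net.card(v) for v in scope)
    return Factor(scope, cpt.table.reshape(shape))


def _multiply(a: Factor, b: Factor) -> Factor:
    scope = a.scope + tuple(v for v in b.scope if v not in a.scope)
    a_ax = [scope.index(v) for v in a.scope]
    b_ax = [scope.index(v) for v in b.scope]
    nd = len(scope)

    def expand(f: Factor, axes) -> np.ndarray:
        order = np.argsort(axes)
        arr = np.transpose(f.values, order)
        slot = [np.newaxis] * nd
        for ax in sorted(axes):
            slot[ax] = slice(None)
        return arr[tuple(slot)]

    return Factor(scope, expand(a, a_ax) * expand(b, b_ax))


def _sum_out(f: Factor, var: str) -> Factor:
    ax = f.scope.index(var)
    return Factor(
        tuple(v for v in f.scope if v != var), f.values.sum(axis=ax)
    )


def _reduce(f: Factor, evidence_idx: dict[str, int]) -> Factor:
    idx = []
    scope = []
    for v in f.scope:
        if v in evidence_idx:
            idx.append(evidence_idx[v])
        else:
            idx.append(slice(None))
            scope.append(v)
    return Factor(tuple(scope), f.values[tuple(idx)])


def _eliminate(
    factors: list[Factor], keep: set[str], order: list[str] | None = None
) -> Factor:
    to_remove = sorted(
        {v for f in factors for v in f.scope} - keep
    )
    if order is not None:
        unknown = set(order) - set(to_remove)
        if unknown:
            raise ValueError(f"order mentions non-eliminable vars {unknown}")
        to_remove = list(order)
    work = list(factors)
    while to_remove:
        if order is None:
            # min-degree: eliminate the variable entangled with fewest others
            def degree(v):
                neigh = set()
                for f in work:
                    if v in f.scope:
                        neigh |= set(f.scope)
                return len(neigh - {v})

            var = min(to_remove, key=lambda v: (degree(v), v))
        else:
            var = to_remove[0]
        to_remove.remove(var)
        involved = [f for f in work if var in f.scope]
        work = [f for f in work if var not in f.scope]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        work.append(_sum_out(prod, var))
    result = Factor((), np.array(1.0))
    for f in work:
        result = _multiply(result, f)
    return result


def query(
    net: BayesNet,
    target: str,
    evidence: dict | None = None,
    *,
    order: list[str] | None = None,
) -> pd.Series:
    """Exact posterior P(target | evidence), indexed by the target's states.

    ``order`` optionally fixes the elimination order (any order gives the
    same posterior); default is the min-degree heuristic.
    """
    evidence = dict(evidence or {})
    if target not in net.dag.nodes:
        raise ValueError(f"unknown target node {target!r}")
    if target in evidence:
        raise ValueError("target node cannot also be evidence")
    ev_idx = {
        v: net.state_index(v, s) for v, s in evidence.items()
    }
    factors = [
        _reduce(_cpt_factor(net, n), ev_idx) for n in net.dag.nodes
    ]
    if order is not None:
        # evidence variables are already reduced away
        order = [v for v in order if v not in evidence and v != target]
    result = _eliminate(factors, keep={target}, order=order)
    if result.scope != (target,):
        ax = result.scope.index(target)
        result = Factor(
            (target,),
            np.moveaxis(result.values, ax, 0).reshape(net.card(target), -1)
            .sum(axis=1),
        )
    total = result.values.sum()
    if total <= 0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability zero under the network"
        )
    return pd.Series(
        result.values / total, index=list(net.states[target]), name=target
    )


def joint_enumeration(net: BayesNet, target: str, evidence: dict | None = None
                      ) -> pd.Series:
    """Brute-force posterior by summing the full joint (small nets only)."""
    import itertools

    evidence = dict(evidence or {})
    nodes = net.dag.nodes
    acc = np.zeros(net.card(target))
    for combo in itertools.product(*(net.states[n] for n in nodes)):
        assign = dict(zip(nodes, combo))
        if any(assign[v] != s for v, s in evidence.items()):
            continue
        p = 1.0
        for n in nodes:
            cpt = net.cpts[n]
            row = net.cpt_row_index(n, assign)
            p *= cpt.table[row, net.state_index(n, assign[n])]
        acc[net.state_index(target, assign[target])] += p
    total = acc.sum()
    if total <= 0:
        raise ImpossibleEvidenceError("evidence has probability zero")
    return pd.Series(acc / total, index=list(net.states[target]), name=target)


def predictive_probability(
    net: BayesNet, disease: str, evidence: dict | None = None, *, yes_state=1
) -> float:
    """P(disease = yes | evidence) for a binary disease node."""
    if net.card(disease) != 2:
        raise ValueError(f"{disease} is not binary")
    post = query(net, disease, evidence)
    return float(post.loc[yes_state])


def diagnostic_profile(
    net: BayesNet, disease: str, state=1
) -> pd.DataFrame:
    """Posterior of every factor node given the disease state, with deltas.

    Clamps the disease node (its probability set to 100%) and reports, for
    every other node and state, the prior probability, the posterior, and
    the signed change in probability.
    """
    if net.card(disease) != 2:
        raise ValueError(f"{disease} is not binary")
    rows = []
    for node in net.dag.nodes:
        if node == disease:
            continue
        prior = query(net, node, {})
        post = query(net, node, {disease: state})
        for s in net.states[node]:
            rows.append(
                {
                    "node": node,
                    "state": s,
                    "prior": float(prior.loc[s]),
                    "posterior": float(post.loc[s]),
                    "delta": float(post.loc[s] - prior.loc[s]),
                }
            )
    return pd.DataFrame(rows)


def classify(
    net: BayesNet,
    disease: str,
    record: dict,
    threshold: float = 0.5,
    *,
    yes_state=1,
) -> tuple[int, float]:
    """Label a (possibly incomplete) record by its disease posterior.

    Unobserved variables are marginalized out, so incomplete records need
    no imputation.  Returns ``(label, probability)`` with label 1 iff the
    posterior exceeds ``threshold``.
    """
    evidence = {
        k: v for k, v in record.items() if k in net.dag.nodes and k != disease
    }
    p = predictive_probability(net, disease, evidence, yes_state=yes_state)
    return (1 if p > threshold else 0, p)
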