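"""Maximum-likelihood CPT estimation for a learned structure.

Pure MLE: theta_ijk = N_ijk / N_ij with no smoothing, so exact 0.000 and
1.000 entries are possible.  Parent configurations never observed in
training receive a uniform row (and a warning) so downstream inference
stays defined; an optional pseudo-count ``smooth`` yields strictly
positive tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bayesnet import CPT, DAG, BayesNet
from .codebook import GROUP_COLUMN


def fit_cpts(
    dag: DAG,
    train: pd.DataFrame,
    *,
    states: dict[str, tuple] | None = None,
    smooth: float = 0.0,
) -> BayesNet:
    """Estimate one CPT per node from a fully discrete training table.

    ``states`` fixes each node's state vocabulary (defaults to the sorted
    unique values observed in ``train``).  ``smooth`` adds that many
    pseudo-counts per cell (0 = pure MLE).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    missing = [n for n in dag.nodes if n not in train.columns]
    if missing:
        raise ValueError(f"nodes absent from data: {missing}")
    if states is None:
        states = {
            n: tuple(np.unique(train[n].to_numpy()).tolist())
            for n in dag.nodes
        }
    codes: dict[str, np.ndarray] = {}
    for n in dag.nodes:
        lookup = {s: i for i, s in enumerate(states[n])}
        try:
            codes[n] = np.array([lookup[v] for v in train[n]], dtype=np.int64)
        except KeyError as err:
            raise ValueError(
                f"{n}: value {err.args[0]!r} outside declared states"
            ) from None
    cpts: dict[str, CPT] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = len(states[node])
        q = int(np.prod([len(states[p]) for p in parents])) if parents else 1
        idx = np.zeros(len(train), dtype=np.int64)
        for p in parents:
            idx = idx * len(states[p]) + codes[p]
        counts = np.bincount(idx * r + codes[node], minlength=q * r)
        counts = counts.reshape(q, r).astype(float)
        row_n = counts.sum(axis=1)
        table = np.empty_like(counts)
        smoothed = counts + smooth
        seen = row_n > 0 if smooth == 0 else np.full(q, True)
        if smooth == 0 and not seen.all():
            warnings.warn(
                f"{node}: {int((~seen).sum())} unseen parent "
                "configuration(s) set to uniform",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            table = smoothed / smoothed.sum(axis=1, keepdims=True)
        table[~seen] = 1.0 / r
        cpts[node] = CPT(
            node=node, parents=parents, table=table, counts=row_n
        )
    return BayesNet(dag=dag, states=states, cpts=cpts)


def network_loglik(net: BayesNet, data: pd.DataFrame) -> float:
    """Total log-likelihood of a discrete table under the network."""
    ll = 0.0
    for node in net.dag.nodes:
        cpt = net.cpts[node]
        child = np.array(
            [net.state_index(node, v) for v in data[node]], dtype=int
        )
        rows = np.zeros(len(data), dtype=int)
        for p in cpt.parents:
            rows = rows * net.card(p) + np.array(
                [net.state_index(p, v) for v in data[p]], dtype=int
            )
        probs = cpt.table[rows, child]
        if np.any(probs <= 0):
            return -np.inf
        ll += float(np.sum(np.log(probs)))
    return ll


def prior_marginals(net: BayesNet) -> dict[str, pd.Series]:
    """Evidence-free marginal distribution of every node."""
    from .inference import query

    return {
        node: query(net, node, evidence={}) for node in net.dag.nodes
    }


def discretized_view(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the group column (helper for learning on case+control data)."""
    return table.drop(columns=[GROUP_COLUMN], errors="ignore")
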