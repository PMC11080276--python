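"""Variance-reduction sensitivity of the disease node to each factor.

With the binary target valued {0, 1}, its prior variance is
V = p(1-p).  Learning a finding node F reduces the expected variance to
E_f[V_f] = sum_f P(f) p_f (1-p_f) with p_f = P(target=1 | F=f); the
sensitivity of the target to F is reported as the percentage

    100 * (V - E_f[V_f]) / V

— the convention used by Netica-style sensitivity-to-findings reports.
An optional mutual-information (entropy-reduction) column is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayesnet import BayesNet
from .inference import query


def variance_reduction(net: BayesNet, target: str, finding: str) -> float:
    """Percentage reduction of the target's prior variance from one finding."""
    if net.card(target) != 2:
        raise ValueError(f"target {target} must be binary")
    if finding == target:
        raise ValueError("finding must differ from the target")
    yes = net.states[target][1]
    p = float(query(net, target, {}).loc[yes])
    v = p * (1 - p)
    if v == 0:
        raise ValueError("degenerate target prior: variance is zero")
    finding_prior = query(net, finding, {})
    expected_v = 0.0
    for s, pf in finding_prior.items():
        if pf <= 0:
            continue
        p_cond = float(query(net, target, {finding: s}).loc[yes])
        expected_v += float(pf) * p_cond * (1 - p_cond)
    return 100.0 * (v - expected_v) / v


def entropy_reduction(net: BayesNet, target: str, finding: str) -> float:
    """Mutual information I(target; finding) in bits (Netica's alternative)."""

    def h(dist: np.ndarray) -> float:
        dist = dist[dist > 0]
        return float(-(dist * np.log2(dist)).sum())

    prior = query(net, target, {}).to_numpy()
    finding_prior = query(net, finding, {})
    cond = 0.0
    for s, pf in finding_prior.items():
        if pf <= 0:
            continue
        cond += float(pf) * h(query(net, target, {finding: s}).to_numpy())
    return h(prior) - cond


def sensitivity_table(
    net: BayesNet, target: str, *, include_entropy: bool = False
) -> pd.DataFrame:
    """Variance reduction of every non-target node, ranked descending.

    Ties are broken by node name so the ranking is deterministic.
    """
    rows = []
    for node in net.dag.nodes:
        if node == target:
            continue
        entry = {
            "variable": node,
            "variance_reduction_pct": variance_reduction(net, target, node),
        }
        if include_entropy:
            entry["mutual_info_bits"] = entropy_reduction(net, target, node)
        rows.append(entry)
    out = pd.DataFrame(rows).sort_values(
        ["variance_reduction_pct", "variable"],
        ascending=[False, True],
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
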