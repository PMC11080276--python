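"""Score-based DAG learning: BIC scoring and tabu search.

The search walks the usual add/delete/reverse single-edge neighborhood
under expert edge constraints (forced and forbidden edges), scoring with
the decomposable BIC

    score(G) = sum_i [ sum_{j,k} N_ijk ln(N_ijk / N_ij) ]
               - (ln N)/2 * sum_i q_i (r_i - 1)

(higher is better; 0 ln 0 = 0).  A short tabu memory of inverse moves with
aspiration lets the search escape local optima; the best structure seen is
returned.  Everything is deterministic for fixed data (ties broken
lexicographically), so the seed only matters for the train/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bayesnet import DAG
from .codebook import GROUP_COLUMN


@dataclass(frozen=True)
class EdgeConstraints:
    """Expert priors: whitelist = forced edges, blacklist = forbidden edges."""

    whitelist: frozenset = frozenset()
    blacklist: frozenset = frozenset()

    def __post_init__(self) -> None:
        wl = frozenset(tuple(e) for e in self.whitelist)
        bl = frozenset(tuple(e) for e in self.blacklist)
        object.__setattr__(self, "whitelist", wl)
        object.__setattr__(self, "blacklist", bl)
        if wl & bl:
            raise ValueError(f"edges both forced and forbidden: {wl & bl}")

    def start_dag(self, nodes) -> DAG:
        return DAG(nodes, self.whitelist)  # raises if whitelist is cyclic


def immutable_blacklist(nodes) -> EdgeConstraints:
    """Default epidemiological constraints: nothing points into fixed traits.

    Age, sex, region and family history are immutable characteristics and
    cannot be effects, so all edges into them are forbidden.
    """
    fixed = {"age", "sex", "area", "fhx_dm", "fhx_cad"}
    bl = {
        (u, v) for v in nodes if v in fixed for u in nodes if u != v
    }
    return EdgeConstraints(blacklist=frozenset(bl))


@dataclass
class SearchParams:
    tenure: int = 10
    max_iter: int = 1000
    stop_window: int = 50  # iterations without improvement before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tenure < 1:
            raise ValueError("tabu tenure must be >= 1")


class BICScorer:
    """Decomposable BIC over a fully discrete table, with a family cache."""

    def __init__(self, data: pd.DataFrame):
        cols = [c for c in data.columns if c != GROUP_COLUMN]
        self.nodes: tuple[str, ...] = tuple(cols)
        self.n = len(data)
        if self.n == 0:
            raise ValueError("empty data")
        self._codes: dict[str, np.ndarray] = {}
        self.cards: dict[str, int] = {}
        self.state_values: dict[str, tuple] = {}
        for c in cols:
            values, codes = np.unique(data[c].to_numpy(), return_inverse=True)
            self._codes[c] = codes.astype(np.int64)
            self.cards[c] = len(values)
            self.state_values[c] = tuple(values.tolist())
        self._cache: dict[tuple, float] = {}

    def family_score(self, child: str, parents: tuple[str, ...]) -> float:
        """BIC contribution of one node given its parent set."""
        key = (child, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        r = self.cards[child]
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in sorted(parents):
            idx = idx * self.cards[p] + self._codes[p]
            q *= self.cards[p]
        counts = np.bincount(idx * r + self._codes[child], minlength=q * r)
        counts = counts.reshape(q, r)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_terms = counts * (np.log(counts) - np.log(row_tot))
        ll = float(np.nansum(np.where(counts > 0, ll_terms, 0.0)))
        score = ll - 0.5 * math.log(self.n) * q * (r - 1)
        self._cache[key] = score
        return score

    def loglik_family(self, child: str, parents: tuple[str, ...]) -> float:
        """Multinomial log-likelihood term alone (no penalty)."""
        r = self.cards[child]
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in sorted(parents):
            idx = idx * self.cards[p] + self._codes[p]
            q *= self.cards[p]
        counts = np.bincount(idx * r + self._codes[child], minlength=q * r)
        counts = counts.reshape(q, r).astype(float)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * (np.log(counts) - np.log(row_tot))
        return float(np.nansum(np.where(counts > 0, terms, 0.0)))

    def total_score(self, dag: DAG) -> float:
        return sum(self.family_score(n, dag.parents(n)) for n in dag.nodes)


@dataclass
class ScoredDAG:
    dag: DAG
    score: float
    family_scores: dict[str, float] = field(default_factory=dict)


Move = tuple[str, str, str]  # (op, u, v) with op in {add, delete, reverse}


def _inverse(move: Move) -> Move:
    op, u, v = move
    if op == "add":
        return ("delete", u, v)
    if op == "delete":
        return ("add", u, v)
    return ("reverse", v, u)


def legal_moves(dag: DAG, constraints: EdgeConstraints) -> list[Move]:
    """All single-edge moves keeping the graph acyclic and constraint-legal."""
    g = dag.to_networkx()
    moves: list[Move] = []
    edge_set = dag.edges
    for u in dag.nodes:
        for v in dag.nodes:
            if u == v:
                continue
            e = (u, v)
            if e in edge_set:
                if e not in constraints.whitelist:
                    moves.append(("delete", u, v))
                rev = (v, u)
                if (
                    e not in constraints.whitelist
                    and rev not in constraints.blacklist
                ):
                    g.remove_edge(u, v)
                    if not nx.has_path(g, u, v):
                        moves.append(("reverse", u, v))
                    g.add_edge(u, v)
            else:
                if e in constraints.blacklist or (v, u) in edge_set:
                    continue
                if not nx.has_path(g, v, u):
                    moves.append(("add", u, v))
    return moves


def _apply(dag: DAG, move: Move) -> DAG:
    op, u, v = move
    if op == "add":
        return dag.with_edge(u, v)
    if op == "delete":
        return dag.without_edge(u, v)
    return dag.reversed_edge(u, v)


def _move_delta(scorer: BICScorer, dag: DAG, move: Move) -> float:
    """Score change of a move, touching only the affected families."""
    op, u, v = move
    old_v = scorer.family_score(v, dag.parents(v))
    if op == "add":
        new_v = scorer.family_score(v, dag.parents(v) + (u,))
        return new_v - old_v
    if op == "delete":
        new_parents = tuple(p for p in dag.parents(v) if p != u)
        return scorer.family_score(v, new_parents) - old_v
    # reverse u->v: v loses parent u, u gains parent v
    old_u = scorer.family_score(u, dag.parents(u))
    new_v = scorer.family_score(v, tuple(p for p in dag.parents(v) if p != u))
    new_u = scorer.family_score(u, dag.parents(u) + (v,))
    return (new_v - old_v) + (new_u - old_u)


def tabu_search(
    data: pd.DataFrame,
    constraints: EdgeConstraints | None = None,
    params: SearchParams | None = None,
    *,
    scorer: BICScorer | None = None,
) -> ScoredDAG:
    """BIC-guided tabu search over DAGs.

    Starts from the whitelist-only graph; each iteration applies the best
    legal move whose inverse is not tabu (aspiration: a tabu move passes if
    it beats the best score seen), pushes the inverse move with the
    configured tenure, and stops after ``max_iter`` iterations or
    ``stop_window`` iterations without improvement.  Returns the best DAG
    encountered.
    """
    constraints = constraints or EdgeConstraints()
    params = params or SearchParams()
    scorer = scorer or BICScorer(data)
    current = constraints.start_dag(scorer.nodes)
    current_score = scorer.total_score(current)
    best_dag, best_score = current, current_score
    tabu_until: dict[Move, int] = {}
    since_improvement = 0
    for it in range(1, params.max_iter + 1):
        candidates = []
        for move in legal_moves(current, constraints):
            delta = _move_delta(scorer, current, move)
            new_score = current_score + delta
            if tabu_until.get(move, 0) >= it and new_score <= best_score:
                continue  # tabu and no aspiration
            candidates.append((-new_score, move))
        if not candidates:
            break
        candidates.sort()  # deterministic: score desc, then move lexicographic
        _, move = candidates[0]
        current = _apply(current, move)
        current_score = scorer.total_score(current)  # cache makes this cheap
        tabu_until[_inverse(move)] = it + params.tenure
        if current_score > best_score + 1e-9:
            best_dag, best_score = current, current_score
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= params.stop_window:
                break
    fam = {n: scorer.family_score(n, best_dag.parents(n))
           for n in best_dag.nodes}
    return ScoredDAG(dag=best_dag, score=best_score, family_scores=fam)


def train_test_split(
    cohort: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified split; per-stratum train size = floor(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    strata = (
        cohort[GROUP_COLUMN]
        if GROUP_COLUMN in cohort.columns
        else pd.Series(0, index=cohort.index)
    )
    for _, idx in sorted(
        cohort.groupby(strata, sort=True).groups.items(),
        key=lambda kv: str(kv[0]),
    ):
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError("stratum smaller than 2")
        perm = rng.permutation(len(idx))
        k = int(math.floor(fraction * len(idx)))
        train_idx.append(idx[perm[:k]])
        test_idx.append(idx[perm[k:]])
    train = cohort.loc[np.concatenate(train_idx)].sort_index()
    test = cohort.loc[np.concatenate(test_idx)].sort_index()
    return train, test


# ---------------------------------------------------------------------------
# CPDAG (Markov-equivalence class) machinery


@dataclass(frozen=True)
class CPDAG:
    """Skeleton plus compelled directions of a DAG's equivalence class."""

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[frozenset]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CPDAG):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.directed,
                     frozenset(self.undirected)))


def v_structures(dag: DAG) -> set[tuple[str, str, str]]:
    """Colliders a->c<-b with a, b nonadjacent, as (a, b, c) with a < b."""
    out = set()
    adj = {frozenset(e) for e in dag.edges}
    for c in dag.nodes:
        ps = dag.parents(c)
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                if frozenset((a, b)) not in adj:
                    out.add((min(a, b), max(a, b), c))
    return out


def cpdag(dag: DAG) -> CPDAG:
    """Equivalence-class representative: v-structure arcs plus Meek closure."""
    adj: dict[str, set[str]] = {n: set() for n in dag.nodes}
    for u, v in dag.edges:
        adj[u].add(v)
        adj[v].add(u)
    directed: set[tuple[str, str]] = set()
    for a, b, c in v_structures(dag):
        if (a, c) in dag.edges:
            directed.add((a, c))
        if (b, c) in dag.edges:
            directed.add((b, c))

    def is_undirected(x, y):
        return y in adj[x] and (x, y) not in directed and (y, x) not in directed

    changed = True
    while changed:
        changed = False
        for x in dag.nodes:
            for y in adj[x]:
                if not is_undirected(x, y):
                    continue
                # Meek R1: z->x, x-y, z,y nonadjacent => x->y
                r1 = any(
                    (z, x) in directed and y not in adj[z]
                    for z in adj[x]
                )
                # Meek R2: x->z->y and x-y => x->y
                r2 = any(
                    (x, z) in directed and (z, y) in directed
                    for z in adj[x] & adj[y]
                )
                # Meek R3: x-z1, x-z2, z1->y, z2->y, z1,z2 nonadjacent => x->y
                r3 = False
                common = [
                    z
                    for z in adj[x] & adj[y]
                    if is_undirected(x, z) and (z, y) in directed
                ]
                for i, z1 in enumerate(common):
                    for z2 in common[i + 1:]:
                        if z2 not in adj[z1]:
                            r3 = True
                if r1 or r2 or r3:
                    directed.add((x, y))
                    changed = True
    undirected = {
        frozenset((u, v))
        for u, v in dag.edges
        if (u, v) not in directed and (v, u) not in directed
    }
    return CPDAG(
        nodes=dag.nodes,
        directed=frozenset(directed),
        undirected=frozenset(undirected),
    )
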