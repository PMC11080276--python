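"""Structure learning: BIC scoring, moves, tabu search, split, CPDAG."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from riskbn.bayesnet import DAG, CyclicGraphError
from riskbn.structure import (
    BICScorer,
    EdgeConstraints,
    SearchParams,
    cpdag,
    legal_moves,
    tabu_search,
    train_test_split,
    v_structures,
)

from conftest import chain_data, collider_data, enumerate_all_dags


def _oracle_total(scorer, nodes, edges):
    parents = {
        n: tuple(sorted(u for u, v in edges if v == n)) for n in nodes
    }
    return sum(scorer.family_score(n, parents[n]) for n in nodes)


class TestBicScore:
    def test_empty_graph_decomposes_into_marginal_families(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            k: (rng.random(500) < 0.5).astype(int) for k in "ABC"
        })
        scorer = BICScorer(df)
        dag = DAG(["A", "B", "C"])
        total = scorer.total_score(dag)
        assert total == pytest.approx(
            sum(scorer.family_score(n, ()) for n in "ABC")
        )

    def test_marginal_family_matches_hand_formula(self):
        """Family score recomputed from the multinomial formula by hand."""
        df = pd.DataFrame({"A": [0] * 300 + [1] * 700})
        scorer = BICScorer(df)
        ll = 300 * math.log(0.3) + 700 * math.log(0.7)
        assert scorer.family_score("A", ()) == pytest.approx(
            ll - 0.5 * math.log(1000) * 1, abs=1e-9
        )

    def test_deterministic_dependence_rewards_the_edge(self):
        rng = np.random.default_rng(1)
        a = (rng.random(1000) < 0.5).astype(int)
        df = pd.DataFrame({"A": a, "B": a})
        scorer = BICScorer(df)
        with_edge = _oracle_total(scorer, ["A", "B"], [("A", "B")])
        without = _oracle_total(scorer, ["A", "B"], [])
        assert with_edge > without

    def test_cache_equals_full_recomputation(self):
        rng = np.random.default_rng(2)
        df = chain_data(rng, 800)
        scorer = BICScorer(df)
        dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        first = scorer.total_score(dag)
        again = BICScorer(df).total_score(dag)
        assert first == pytest.approx(again, abs=1e-9)


class TestLegalMoves:
    def test_two_nodes_no_edges(self):
        dag = DAG(["A", "B"])
        moves = legal_moves(dag, EdgeConstraints())
        assert sorted(moves) == [("add", "A", "B"), ("add", "B", "A")]

    def test_three_nodes_empty_graph_has_six_additions(self):
        dag = DAG(["A", "B", "C"])
        moves = legal_moves(dag, EdgeConstraints())
        assert len(moves) == 6
        assert all(op == "add" for op, _, _ in moves)

    def test_cycle_completing_addition_excluded(self):
        dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        moves = legal_moves(dag, EdgeConstraints())
        assert ("add", "C", "A") not in moves
        assert ("add", "A", "C") in moves

    def test_constraints_respected(self):
        dag = DAG(["A", "B"], [("A", "B")])
        cons = EdgeConstraints(whitelist={("A", "B")},
                               blacklist={("B", "A")})
        moves = legal_moves(dag, cons)
        assert moves == []  # cannot delete forced edge nor reverse into ban

    def test_inconsistent_constraints_rejected(self):
        with pytest.raises(ValueError, match="forced and forbidden"):
            EdgeConstraints(whitelist={("A", "B")}, blacklist={("A", "B")})

    def test_cyclic_whitelist_rejected(self):
        cons = EdgeConstraints(whitelist={("A", "B"), ("B", "A")})
        with pytest.raises(CyclicGraphError):
            cons.start_dag(["A", "B"])


class TestTabuSearch:
    @pytest.mark.parametrize("maker", [chain_data, collider_data])
    def test_attains_exhaustive_optimum(self, maker):
        rng = np.random.default_rng(7)
        df = maker(rng, 4000)
        scorer = BICScorer(df)
        oracle_best = max(
            _oracle_total(scorer, list("ABC"), edges)
            for edges in enumerate_all_dags(list("ABC"))
        )
        result = tabu_search(df, scorer=scorer)
        assert result.score == pytest.approx(oracle_best, abs=1e-9)

    def test_chain_recovers_chain_cpdag(self):
        rng = np.random.default_rng(8)
        result = tabu_search(chain_data(rng, 5000))
        truth = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert cpdag(result.dag) == cpdag(truth)

    def test_vstructure_recovered_exactly(self):
        rng = np.random.default_rng(9)
        result = tabu_search(collider_data(rng, 5000))
        assert result.dag.edges == frozenset({("A", "C"), ("B", "C")})

    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            k: (rng.random(5000) < 0.5).astype(int) for k in "ABC"
        })
        result = tabu_search(df)
        assert result.dag.edges == frozenset()

    def test_whitelisted_edge_kept_blacklisted_absent(self):
        rng = np.random.default_rng(11)
        df = chain_data(rng, 3000)
        cons = EdgeConstraints(whitelist={("A", "B")},
                               blacklist={("B", "C"), ("C", "B")})
        result = tabu_search(df, cons)
        assert ("A", "B") in result.dag.edges
        assert ("B", "C") not in result.dag.edges
        assert ("C", "B") not in result.dag.edges

    def test_deterministic_for_fixed_data(self):
        rng = np.random.default_rng(12)
        df = chain_data(rng, 2000)
        r1 = tabu_search(df)
        r2 = tabu_search(df)
        assert r1.dag == r2.dag and r1.score == r2.score

    def test_family_scores_sum_to_total(self):
        rng = np.random.default_rng(13)
        result = tabu_search(chain_data(rng, 1000))
        assert sum(result.family_scores.values()) == pytest.approx(
            result.score, abs=1e-9
        )


class TestTrainTestSplit:
    def test_published_split_arithmetic(self):
        """1175 controls + 1163 cases at 70% -> 822+814 train, 353+349 test."""
        df = pd.DataFrame({
            "group": ["control"] * 1175 + ["T2DM"] * 1163,
            "x": np.arange(2338),
        })
        train, test = train_test_split(df, 0.7, seed=1)
        tc = train["group"].value_counts()
        sc = test["group"].value_counts()
        assert (tc["control"], tc["T2DM"]) == (822, 814)
        assert (sc["control"], sc["T2DM"]) == (353, 349)

    def test_disjoint_exhaustive_and_seeded(self):
        df = pd.DataFrame({
            "group": ["control"] * 50 + ["CAD"] * 40,
            "x": np.arange(90),
        })
        tr1, te1 = train_test_split(df, 0.7, seed=5)
        tr2, te2 = train_test_split(df, 0.7, seed=5)
        pd.testing.assert_frame_equal(tr1, tr2)
        assert set(tr1["x"]) | set(te1["x"]) == set(df["x"])
        assert set(tr1["x"]) & set(te1["x"]) == set()
        tr3, _ = train_test_split(df, 0.7, seed=6)
        assert not tr1.equals(tr3)

    def test_bad_fraction_and_small_stratum_rejected(self):
        df = pd.DataFrame({"group": ["control", "control", "CAD"],
                           "x": [1, 2, 3]})
        with pytest.raises(ValueError, match="fraction"):
            train_test_split(df, 1.5, seed=0)
        with pytest.raises(ValueError, match="stratum"):
            train_test_split(df, 0.7, seed=0)


class TestCpdag:
    def test_chain_fully_undirected(self):
        dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        result = cpdag(dag)
        assert result.directed == frozenset()
        assert result.undirected == {
            frozenset({"A", "B"}), frozenset({"B", "C"})
        }

    def test_vstructure_stays_directed(self):
        dag = DAG(["A", "B", "C"], [("A", "C"), ("B", "C")])
        result = cpdag(dag)
        assert result.directed == {("A", "C"), ("B", "C")}
        assert result.undirected == frozenset()

    def test_meek_propagation_beyond_collider(self):
        # A->C<-B plus C->D: C->D is compelled (else a new collider at C)
        dag = DAG("ABCD", [("A", "C"), ("B", "C"), ("C", "D")])
        result = cpdag(dag)
        assert ("C", "D") in result.directed

    def test_equivalence_classes_map_to_identical_cpdags(self):
        """Oracle: DAGs with equal skeleton+v-structures share a CPDAG."""
        rng = np.random.default_rng(20)
        nodes = list("ABCDE")
        for _ in range(10):
            edges = [
                (nodes[i], nodes[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            dag = DAG(nodes, edges)
            skel = {frozenset(e) for e in dag.edges}
            vs = v_structures(dag)
            reference = cpdag(dag)
            # brute force: every acyclic reorientation of the skeleton
            n_equivalent = 0
            for flips in itertools.product((0, 1), repeat=len(edges)):
                other_edges = [
                    (v, u) if f else (u, v)
                    for (u, v), f in zip(edges, flips)
                ]
                try:
                    other = DAG(nodes, other_edges)
                except CyclicGraphError:
                    continue
                if v_structures(other) != vs:
                    continue
                n_equivalent += 1
                assert cpdag(other) == reference
            assert n_equivalent >= 1  # the original DAG itself
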