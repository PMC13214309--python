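import numpy as np
import pytest
from scipy import stats

from hubdrug.enrichment import (
    GeneSet,
    enrich,
    hypergeometric_test,
    kappa_score,
    read_gmt,
    term_network,
    write_gmt,
)
from oracles import hypergeom_tail_by_summation


class TestHypergeometricTest:
    def test_degenerate_cases(self):
        assert hypergeometric_test(0, 5, 4, 10) == pytest.approx(1.0)
        assert hypergeometric_test(4, 10, 4, 10) == pytest.approx(1.0)  # K=N forces k=n

    def test_exhaustive_enumeration_example(self):
        # k=4, K=5, n=4, N=10: 5 favorable draws of C(10,4)=210
        assert hypergeometric_test(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(6, 5, 6, 10)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 11, 4, 10)

    def test_pmf_sums_to_one_and_matches_summation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            N = int(rng.integers(5, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            total = sum(
                hypergeom_tail_by_summation(i, K, n, N)
                - hypergeom_tail_by_summation(i + 1, K, n, N)
                for i in range(0, min(K, n) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_test(k, K, n, N) == pytest.approx(
                hypergeom_tail_by_summation(k, K, n, N), rel=1e-10
            )

    def test_matches_one_sided_fisher(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            N = int(rng.integers(8, 50))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            fisher = stats.fisher_exact(table, alternative="greater").pvalue
            assert hypergeometric_test(k, K, n, N) == pytest.approx(fisher, abs=1e-10)


class TestEnrich:
    def _collection(self):
        return [
            GeneSet("T1", "hit", frozenset({"a", "b", "c", "d"})),
            GeneSet("T2", "small overlap", frozenset({"a", "b", "x", "y", "z"})),
            GeneSet("T3", "background", frozenset({"u", "v", "w"})),
        ]

    def test_min_genes_rule(self):
        universe = {c for c in "abcdxyzuvw"} | {f"q{i}" for i in range(40)}
        res = enrich({"a", "b", "c", "d"}, self._collection(), universe)
        assert "T2" not in set(res["term_id"])  # k=2 overlap never tested
        assert res.iloc[0]["term_id"] == "T1"

    def test_query_equals_universe_gives_p_one(self):
        universe = {"a", "b", "c", "d", "u", "v", "w"}
        res = enrich(universe, self._collection(), universe, alpha=1.1)
        assert np.allclose(res["p"], 1.0)

    def test_planted_set_ranks_first(self, small_config):
        from hubdrug.simulate import simulate_expression, simulate_gene_sets

        _, _, truth = simulate_expression(small_config)
        collection = simulate_gene_sets(small_config, truth)
        universe = {f"G{i:06d}" for i in range(1, small_config.n_genes + 1)}
        res = enrich(set(truth.de_genes), collection, universe)
        assert res.iloc[0]["term_id"] == "T00000"

    def test_sorted_p_and_adj_at_least_p(self):
        universe = {c for c in "abcdxyzuvw"} | {f"q{i}" for i in range(40)}
        res = enrich({"a", "b", "c", "d", "u", "v", "w"}, self._collection(), universe, alpha=1.1)
        assert list(res["p"]) == sorted(res["p"])
        assert np.all(res["adj_p"].to_numpy() >= res["p"].to_numpy() - 1e-15)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"a"}, self._collection(), set())


class TestKappa:
    def test_identical_sets(self):
        assert kappa_score({"a", "b"}, {"a", "b"}, set("abcdef")) == pytest.approx(1.0)

    def test_disjoint_hand_table(self):
        # 2x2 table (0,5,5,90) over universe 100 -> kappa = -1/19
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 10)}
        assert kappa_score(a, b, universe) == pytest.approx(-1 / 19, rel=1e-9)

    def test_degenerate_returns_zero(self):
        u = {"a", "b"}
        assert kappa_score(u, u, u) == 0.0
        assert kappa_score(set(), set(), u) == 0.0

    def test_independent_sets_near_zero(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(100)]
        vals = [
            kappa_score(
                set(rng.choice(universe, 20, replace=False)),
                set(rng.choice(universe, 20, replace=False)),
                universe,
            )
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02


class TestTermNetwork:
    def test_edges_from_membership_kappa(self):
        universe = {f"g{i}" for i in range(50)}
        shared = frozenset(list(universe)[:10])
        collection = [
            GeneSet("T1", "x", shared),
            GeneSet("T2", "y", shared),
            GeneSet("T3", "z", frozenset(list(universe)[20:25])),
        ]
        res = enrich(set(shared) | set(list(universe)[20:25]), collection, universe, alpha=1.1)
        net = term_network(res, collection, universe)
        assert net.has_edge("T1", "T2")  # identical membership, kappa 1
        assert not net.has_edge("T1", "T3")
        strict = term_network(res, collection, universe, kappa_min=1.0)
        assert strict.number_of_edges() == 0  # kappa must exceed 1: impossible

    def test_single_term(self):
        universe = {"a", "b", "c", "d"}
        collection = [GeneSet("T1", "x", frozenset({"a", "b", "c"}))]
        res = enrich({"a", "b", "c"}, collection, universe, alpha=1.1)
        net = term_network(res, collection, universe)
        assert set(net.nodes) == {"T1"} and net.number_of_edges() == 0


def test_gmt_round_trip(tmp_path):
    collection = [
        GeneSet("T1", "first process", frozenset({"a", "b", "c"})),
        GeneSet("T2", "second", frozenset({"x", "y", "z", "w"})),
    ]
    path = tmp_path / "sets.gmt"
    write_gmt(collection, path)
    back = read_gmt(path)
    assert {(s.term_id, s.term_name, s.genes) for s in back} == {
        (s.term_id, s.term_name, s.genes) for s in collection
    }


def test_empty_gene_set_rejected():
    with pytest.raises(ValueError):
        GeneSet("T", "empty", frozenset())
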