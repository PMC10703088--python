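import numpy as np
import pytest

from genecompete.competition import CompetitionConfig, build_competition
from genecompete.errors import DegenerateCompetitionError
from genecompete.rankers import (
    METHODS,
    RankerParams,
    keener_skew,
    rank_all,
    rank_bipagerank,
    rank_colley,
    rank_elo,
    rank_keener,
    rank_markov,
    rank_massey,
    rank_pagerank,
    rank_winloss,
)

from conftest import make_table, random_competition, zero_competition
from _oracles import dense_markov, dense_pagerank


def vec(res, cm):
    return np.asarray([res.scores[g] for g in cm.genes])


class TestWinLoss:
    def test_union_hand_example(self):
        d1 = make_table("d1", {"A": 2.0, "B": 1.0, "C": -0.5})
        d2 = make_table("d2", {"B": 3.0, "C": 1.0})
        cm = build_competition([d1, d2], CompetitionConfig(strategy="union"))
        res = rank_winloss(cm)
        assert res.scores == {"A": 2.0, "B": 1.0, "C": 0.0}

    def test_single_dataset(self, two_gene_cm):
        res = rank_winloss(two_gene_cm)
        assert res.scores == {"A": 1.0, "B": 0.0}
        assert res.ranks == {"A": 1.0, "B": 2.0}

    def test_all_tie_double_win(self):
        cm = build_competition(
            [make_table("d", {"A": 1.0, "B": 1.0})], CompetitionConfig()
        )
        assert rank_winloss(cm).scores == {"A": 1.0, "B": 1.0}

    def test_intersection_matches_total_wins_ordering(self, rng):
        cm = random_competition(rng, n_genes=15, k=3)
        res = rank_winloss(cm)
        totals = cm.W.sum(axis=1)
        order_ratio = np.argsort(-vec(res, cm), kind="stable")
        order_total = np.argsort(-totals, kind="stable")
        assert np.array_equal(order_ratio, order_total)


class TestMassey:
    def test_two_gene_hand_solution(self, two_gene_cm):
        res = rank_massey(two_gene_cm)
        assert res.scores["A"] == pytest.approx(0.5)
        assert res.scores["B"] == pytest.approx(-0.5)

    def test_zero_sum(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=12, k=3)
            s = sum(rank_massey(cm).scores.values())
            assert abs(s) < 1e-8 * cm.N

    def test_no_games_all_zero(self):
        res = rank_massey(zero_competition(4))
        assert all(v == pytest.approx(0.0) for v in res.scores.values())

    def test_degenerate(self):
        with pytest.raises(DegenerateCompetitionError):
            rank_massey(zero_competition(1))


class TestColley:
    def test_no_games_all_half(self):
        res = rank_colley(zero_competition(6))
        assert all(v == 0.5 for v in res.scores.values())

    def test_two_gene_hand_solution(self, two_gene_cm):
        res = rank_colley(two_gene_cm)
        assert res.scores["A"] == pytest.approx(0.625)
        assert res.scores["B"] == pytest.approx(0.375)

    def test_sum_is_half_n(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=11, k=4)
            assert sum(rank_colley(cm).scores.values()) == pytest.approx(
                cm.N / 2, abs=1e-8
            )


class TestKeenerSkew:
    def test_fixed_points(self):
        assert keener_skew(0.5) == 0.5
        assert keener_skew(0.0) == 0.0
        assert keener_skew(1.0) == 1.0

    def test_two_thirds(self):
        assert keener_skew(2 / 3) == pytest.approx(0.5 + 0.5 * np.sqrt(1 / 3))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            keener_skew(1.2)

    def test_antisymmetry(self, rng):
        x = rng.random(100)
        assert np.allclose(keener_skew(x) + keener_skew(1 - x), 1.0)


class TestKeener:
    def test_two_gene_closed_form(self, two_gene_cm):
        # dominant eigenvector of a 2x2 antidiagonal matrix is
        # (sqrt(K_AB), sqrt(K_BA)), normalized
        res = rank_keener(two_gene_cm)
        kab = keener_skew(2 / 3)
        kba = keener_skew(1 / 3)
        expect_a = np.sqrt(kab) / (np.sqrt(kab) + np.sqrt(kba))
        assert res.scores["A"] == pytest.approx(expect_a, abs=1e-8)
        assert res.scores["B"] == pytest.approx(1 - expect_a, abs=1e-8)

    def test_no_games_uniform(self):
        res = rank_keener(zero_competition(5))
        assert all(v == pytest.approx(0.2) for v in res.scores.values())

    def test_positive_and_sums_to_one(self, rng):
        cm = random_competition(rng, n_genes=10, k=3, strategy="union",
                                presence=0.7)
        v = vec(rank_keener(cm), cm)
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(1.0, abs=1e-10)


class TestElo:
    def test_equal_ratings_single_win(self, two_gene_cm):
        res = rank_elo(two_gene_cm)
        assert res.scores == {"A": 1505.0, "B": 1495.0}

    def test_tie_leaves_ratings_unchanged(self):
        cm = build_competition(
            [make_table("d", {"A": 1.0, "B": 1.0})], CompetitionConfig()
        )
        assert rank_elo(cm).scores == {"A": 1500.0, "B": 1500.0}

    def test_tie_free_zero_sum(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=9, k=3)
            total = sum(rank_elo(cm).scores.values())
            assert total == pytest.approx(1500.0 * cm.N, abs=1e-6)

    def test_down_mode_flips_winner(self):
        t = make_table("d", {"A": 2.0, "B": 1.0})
        cm = build_competition([t], CompetitionConfig(regulation="down"))
        res = rank_elo(cm)
        assert res.scores["B"] > res.scores["A"]


class TestMarkov:
    def test_two_gene_hand_solution(self, two_gene_cm):
        res = rank_markov(two_gene_cm)
        assert res.scores["A"] == pytest.approx(2 / 3, abs=1e-8)
        assert res.scores["B"] == pytest.approx(1 / 3, abs=1e-8)

    def test_no_games_uniform(self):
        res = rank_markov(zero_competition(4))
        assert all(v == pytest.approx(0.25) for v in res.scores.values())

    def test_stationary_matches_dense_eig(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=6, k=2)
            got = vec(rank_markov(cm), cm)
            want = dense_markov(cm.L)
            assert np.allclose(got, want, atol=1e-8)


class TestPageRank:
    def test_two_gene_hand_solution(self, two_gene_cm):
        res = rank_pagerank(two_gene_cm)
        assert res.scores["A"] == pytest.approx(0.925 / 1.425, abs=1e-8)
        assert res.scores["B"] == pytest.approx(0.5 / 1.425, abs=1e-8)

    def test_no_games_uniform(self):
        res = rank_pagerank(zero_competition(5))
        assert all(v == pytest.approx(0.2) for v in res.scores.values())

    def test_matches_dense_eig(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=6, k=3, strategy="union",
                                    presence=0.8)
            got = vec(rank_pagerank(cm), cm)
            want = dense_pagerank(cm.L, alpha=0.85)
            assert np.allclose(got, want, atol=1e-8)

    def test_positive_sums_to_one(self, rng):
        cm = random_competition(rng, n_genes=12, k=3)
        v = vec(rank_pagerank(cm), cm)
        assert np.all(v > 0) and v.sum() == pytest.approx(1.0, abs=1e-10)


class TestBiPageRank:
    def test_head_to_head_symmetric_is_zero(self):
        d1 = make_table("d1", {"A": 2.0, "B": 1.0})
        d2 = make_table("d2", {"A": 1.0, "B": 2.0})
        cm = build_competition([d1, d2], CompetitionConfig())
        res = rank_bipagerank(cm)
        assert res.scores["A"] == pytest.approx(0.0, abs=1e-9)
        assert res.scores["B"] == pytest.approx(0.0, abs=1e-9)

    def test_two_gene_hand_solution(self, two_gene_cm):
        res = rank_bipagerank(two_gene_cm)
        expect = 0.925 / 1.425 - 0.5 / 1.425
        assert res.scores["A"] == pytest.approx(expect, abs=1e-8)
        assert res.scores["B"] == pytest.approx(-expect, abs=1e-8)

    def test_zero_sum(self, rng):
        for _ in range(5):
            cm = random_competition(rng, n_genes=10, k=3, strategy="union",
                                    presence=0.8)
            assert sum(rank_bipagerank(cm).scores.values()) == pytest.approx(
                0.0, abs=1e-10
            )


class TestRankAll:
    def test_single_method(self, two_gene_cm):
        results = rank_all(two_gene_cm, ["winloss"])
        assert len(results) == 1 and results[0].method == "winloss"

    def test_all_methods_share_universe(self, rng):
        cm = random_competition(rng, n_genes=20, k=3)
        results = rank_all(cm)
        assert [r.method for r in results] == list(METHODS)
        for r in results:
            assert set(r.scores) == set(cm.genes)
            assert set(r.ranks) == set(cm.genes)

    def test_unknown_method(self, two_gene_cm):
        with pytest.raises(ValueError, match="unknown"):
            rank_all(two_gene_cm, ["winloss", "nope"])

    def test_duplicates_deduplicated(self, two_gene_cm):
        results = rank_all(two_gene_cm, ["winloss", "winloss"])
        assert len(results) == 1

    def test_wall_times_recorded(self, two_gene_cm):
        for r in rank_all(two_gene_cm):
            assert r.wall_time >= 0


class TestCrossMethodProperties:
    def test_permutation_equivariance(self, rng):
        cm = random_competition(rng, n_genes=8, k=3)
        # relabel genes with reversed names: candidate order changes
        mapping = {g: f"z{len(cm.genes) - i:02d}" for i, g in enumerate(cm.genes)}
        tables = [
            make_table(f"p{d}", {mapping[g]: s for g, s in scores.items()})
            for d, scores in enumerate(cm.per_dataset)
        ]
        cm2 = build_competition(tables, CompetitionConfig())
        # elo is excluded: its deterministic lexicographic match order is
        # itself label-dependent, so relabeling reorders its updates
        methods = [m for m in METHODS if m != "elo"]
        for res1, res2 in zip(rank_all(cm, methods), rank_all(cm2, methods)):
            for g in cm.genes:
                assert res2.scores[mapping[g]] == pytest.approx(
                    res1.scores[g], abs=1e-9
                )

    def test_outcome_only_dependence(self, rng):
        # doubling all magnitudes changes no pairwise order, hence no score
        cm = random_competition(rng, n_genes=8, k=3)
        tables = [
            make_table(f"s{d}", {g: 2.0 * s for g, s in scores.items()})
            for d, scores in enumerate(cm.per_dataset)
        ]
        cm2 = build_competition(tables, CompetitionConfig())
        for res1, res2 in zip(rank_all(cm), rank_all(cm2)):
            for g in cm.genes:
                assert res2.scores[g] == pytest.approx(res1.scores[g], abs=1e-9)

    def test_single_dataset_concordance_all_methods(self, rng):
        # no-tie single dataset: every method must reproduce the logFC order
        for _ in range(10):
            n = int(rng.integers(3, 9))
            scores = {f"g{i}": float(v)
                      for i, v in enumerate(rng.normal(0, 2, size=n))}
            cm = build_competition(
                [make_table("d", scores)], CompetitionConfig()
            )
            want = sorted(scores, key=scores.get, reverse=True)
            for res in rank_all(cm):
                got = sorted(scores, key=lambda g: res.ranks[g])
                assert got == want, f"{res.method} broke concordance"
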