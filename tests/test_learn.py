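"""The bcDBN learner, the tDBN baseline and their optimality guarantees."""

import itertools

import numpy as np
import pytest

from bcdbn.branching import bfs_total_order, max_branching
from bcdbn.learn import (
    LearnConfig,
    best_past_set,
    compute_edge_weights,
    enumerate_subsets,
    learn,
    learn_tdbn,
    learn_transition,
    make_scorer,
    past_pool,
    select_parents,
    structure_score,
)
from bcdbn.model import SlicedVariable, canonical_parents
from bcdbn.scores import ScoreSpec

from conftest import copy_dataset, naive_local_score, random_dataset


class TestEnumerateSubsets:
    def test_small_pool(self):
        subs = list(enumerate_subsets([0, 1, 2], 2))
        assert len(subs) == 7
        assert subs[0] == ()
        assert subs[1:4] == [(0,), (1,), (2,)]

    def test_binomial_sum(self):
        assert len(list(enumerate_subsets(list(range(10)), 2))) == 56

    def test_max_zero(self):
        assert list(enumerate_subsets([0, 1], 0)) == [()]


class TestBestPastSet:
    def test_p_zero_returns_empty(self, rng):
        data = random_dataset(rng, n=3, N=10)
        cfg = LearnConfig(p=0, k=0, score=ScoreSpec("ll"))
        pset, _ = best_past_set(1, None, data, cfg)
        assert pset == frozenset()

    def test_copy_process_finds_own_past(self, rng):
        data = copy_dataset(rng, n=3, N=30)
        cfg = LearnConfig(p=1, score=ScoreSpec("ll"))
        pset, score = best_past_set(1, None, data, cfg)
        assert pset == frozenset({SlicedVariable(1, 0)})
        assert score == 0.0

    def test_matches_bruteforce(self, rng):
        for trial in range(10):
            n = int(rng.integers(2, 4))
            p = int(rng.integers(0, 3))
            data = random_dataset(rng, n=n, N=int(rng.integers(8, 40)))
            crit = "mdl" if trial % 2 else "ll"
            cfg = LearnConfig(p=p, score=ScoreSpec(crit))
            scorer = make_scorer(data, cfg)
            _, got = best_past_set(0, None, data, cfg, scorer=scorer)
            rows = [tuple(r) for r in scorer.table.rows]
            best = max(
                naive_local_score(rows, data.cards, 1, n, 0, canonical_parents(sub), crit)
                for sub in enumerate_subsets(past_pool(n, 1), p)
            )
            assert got == pytest.approx(best, abs=1e-9)


class TestEdgeWeights:
    def test_gain_identity(self, rng):
        data = random_dataset(rng, n=3, N=25)
        cfg = LearnConfig(p=1, score=ScoreSpec("mdl"))
        ew = compute_edge_weights(data, cfg)
        for j in range(3):
            for i in range(3):
                if i != j:
                    assert ew.e[j, i] == ew.s_pair[j, i] - ew.s[i]

    def test_copy_process_gains_nonpositive(self, rng):
        """With a perfect past parent (LL = 0) no intra edge can help."""
        data = copy_dataset(rng, n=2, N=30)
        cfg = LearnConfig(p=1, score=ScoreSpec("ll"))
        ew = compute_edge_weights(data, cfg)
        assert ew.e[0, 1] <= 1e-12 and ew.e[1, 0] <= 1e-12

    def test_independent_noise_mdl_gains_negative(self, rng):
        data = random_dataset(rng, n=3, N=200)
        cfg = LearnConfig(p=1, score=ScoreSpec("mdl"))
        ew = compute_edge_weights(data, cfg)
        off = ew.e[~np.eye(3, dtype=bool)]
        assert np.all(off < 0)


class TestSelectParents:
    def test_root_gets_empty_intra(self, rng):
        data = random_dataset(rng, n=3, N=20)
        cfg = LearnConfig(p=1, k=2, score=ScoreSpec("mdl"))
        pset, iset, score = select_parents(0, frozenset(), data, cfg)
        assert iset == frozenset()
        bset, bscore = best_past_set(0, None, data, cfg)
        assert (pset, score) == (bset, bscore)

    def test_matches_bruteforce_product_space(self, rng):
        for trial in range(10):
            n = int(rng.integers(2, 5))
            p = int(rng.integers(0, 3))
            k = int(rng.integers(0, 3))
            data = random_dataset(rng, n=n, N=int(rng.integers(10, 40)))
            crit = "mdl" if trial % 2 else "ll"
            cfg = LearnConfig(p=p, k=k, score=ScoreSpec(crit))
            child = 0
            ancestors = frozenset(range(1, n))
            scorer = make_scorer(data, cfg)
            _, _, got = select_parents(child, ancestors, data, cfg, scorer=scorer)
            rows = [tuple(r) for r in scorer.table.rows]
            best = max(
                naive_local_score(
                    rows, data.cards, 1, n, child,
                    canonical_parents(
                        past + tuple(SlicedVariable(j, 1) for j in intra)
                    ),
                    crit,
                )
                for past in enumerate_subsets(past_pool(n, 1), p)
                for intra in enumerate_subsets(sorted(ancestors), k)
            )
            assert got == pytest.approx(best, abs=1e-9)


class TestLearnTransition:
    def test_single_attribute_has_no_intra_edges(self, rng):
        data = random_dataset(rng, n=1, N=20)
        struct = learn_transition(data, LearnConfig(p=1, k=1))
        assert struct.intra_parents == (frozenset(),)

    def test_optimal_in_bfs_consistent_space(self, rng):
        """The learned structure attains the exhaustive optimum over all
        structures BFS-consistent with the learner's own order."""
        for trial in range(10):
            n = int(rng.integers(2, 5))
            p = int(rng.integers(0, 3))
            k = int(rng.integers(0, 3))
            data = random_dataset(rng, n=n, N=int(rng.integers(10, 50)))
            crit = "mdl" if trial % 2 else "ll"
            cfg = LearnConfig(p=p, k=k, score=ScoreSpec(crit))
            scorer = make_scorer(data, cfg)
            struct = learn_transition(data, cfg, scorer=scorer)
            struct.validate_bounds(cfg.p, cfg.k)
            got = structure_score(struct, data, cfg, scorer=scorer)
            ew = compute_edge_weights(data, cfg, scorer=scorer)
            order = bfs_total_order(max_branching(ew.e, cfg.branching_mode))
            rows = [tuple(r) for r in scorer.table.rows]
            expected = 0.0
            for i in range(n):
                expected += max(
                    naive_local_score(
                        rows, data.cards, 1, n, i,
                        canonical_parents(
                            past + tuple(SlicedVariable(j, 1) for j in intra)
                        ),
                        crit,
                    )
                    for past in enumerate_subsets(past_pool(n, 1), p)
                    for intra in enumerate_subsets(sorted(order.ancestors[i]), k)
                )
            assert got == pytest.approx(expected, abs=1e-9)

    def test_determinism(self, rng):
        data = random_dataset(rng, n=4, N=40)
        cfg = LearnConfig(p=2, k=2, score=ScoreSpec("mdl"))
        a = learn_transition(data, cfg)
        b = learn_transition(data, cfg)
        assert a == b

    def test_polynomial_scaling_of_score_evaluations(self, rng):
        """Doubling n at p = k = 1 grows the number of distinct score
        evaluations by a bounded polynomial factor, not exponentially."""
        evals = {}
        for n in (4, 8):
            data = random_dataset(rng, n=n, N=30)
            cfg = LearnConfig(p=1, k=1, score=ScoreSpec("mdl"))
            scorer = make_scorer(data, cfg)
            learn_transition(data, cfg, scorer=scorer)
            evals[n] = scorer.evaluations
        assert evals[8] / evals[4] < 2 ** (1 + 1 + 2)


class TestTDBN:
    def test_two_nodes_have_one_intra_edge(self, rng):
        data = random_dataset(rng, n=2, N=30)
        struct = learn_tdbn(data, LearnConfig(p=1))
        assert sum(len(s) for s in struct.intra_parents) == 1

    def test_score_identity(self, rng):
        """tDBN total score = branching weight + sum_i s_i, exactly."""
        for _ in range(10):
            n = int(rng.integers(2, 5))
            data = random_dataset(rng, n=n, N=int(rng.integers(15, 60)))
            cfg = LearnConfig(p=1, score=ScoreSpec("mdl"))
            scorer = make_scorer(data, cfg)
            struct = learn_tdbn(data, cfg, scorer=scorer)
            ew = compute_edge_weights(data, cfg, scorer=scorer)
            br = max_branching(ew.e, "spanning")
            total = structure_score(struct, data, cfg, scorer=scorer)
            assert total == pytest.approx(br.total_weight + ew.s.sum(), abs=1e-9)

    def test_bcdbn_dominates_tdbn(self, rng):
        """bcDBN with k >= 1 searches a superset of tDBN structures."""
        for _ in range(10):
            n = int(rng.integers(2, 5))
            data = random_dataset(rng, n=n, N=int(rng.integers(15, 60)))
            cfg = LearnConfig(p=1, k=1, score=ScoreSpec("mdl"))
            scorer = make_scorer(data, cfg)
            bc = structure_score(
                learn_transition(data, cfg, scorer=scorer), data, cfg, scorer=scorer
            )
            td = structure_score(
                learn_tdbn(data, cfg, scorer=scorer), data, cfg, scorer=scorer
            )
            assert bc >= td - 1e-9


class TestLearnFullModel:
    def test_stationary_single_window_equivalence(self, rng):
        data = random_dataset(rng, n=3, N=25, T=1)
        cfg = LearnConfig(p=1, k=1)
        model = learn(data, cfg)
        assert len(model.transitions) == 1
        assert model.transitions[0][0] == learn_transition(data, cfg)

    def test_non_stationary_window_count(self, rng):
        data = random_dataset(rng, n=2, N=25, T=1)
        cfg = LearnConfig(p=1, k=1, stationary=False)
        model = learn(data, cfg)
        assert len(model.transitions) == 1  # T = m gives exactly one window
        data2 = random_dataset(rng, n=2, N=25, T=3)
        model2 = learn(data2, LearnConfig(p=1, k=1, stationary=False))
        assert len(model2.transitions) == 3

    def test_too_short_series_rejected(self, rng):
        data = random_dataset(rng, n=2, N=5, T=1)
        with pytest.raises(ValueError):
            learn(data, LearnConfig(m=2, p=1, k=1))

    def test_learned_cpts_are_valid(self, rng):
        data = random_dataset(rng, n=3, N=30)
        model = learn(data, LearnConfig(p=1, k=1))
        _, cpts = model.transitions[0]
        for cpt in cpts.values():
            assert np.allclose(cpt.table.sum(axis=1), 1.0)


class TestSearchSpaceCount:
    def test_bfs_consistent_graph_count_for_chain(self):
        """For a chain branching the number of BFS-consistent k-graphs is
        the product over nodes of the subset counts of their prefixes, and
        dominates the 2^(nk - k^2/2 - k/2) lower bound."""
        n, k = 4, 1
        per_node = [
            len(list(enumerate_subsets(list(range(i)), k))) for i in range(n)
        ]
        total = int(np.prod(per_node))
        assert per_node == [1, 2, 3, 4] and total == 24
        assert total >= 2 ** (n * k - k * k / 2 - k / 2)
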