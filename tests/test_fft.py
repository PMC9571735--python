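"""Tree induction: marginal splits, cue ranking, ifan/dfan construction."""

import numpy as np
import pandas as pd
import pytest

from _bruteforce import (dfan_greedy_goal, dfan_oracle_goal, ifan_oracle_goal,
                         naive_best_rule)
from conftest import make_table
from podtree import (FastFrugalTreeModel, best_split_for_cue, build_dfan,
                     build_ifan, default_planted_config, default_planted_tree,
                     generate_planted, rank_cues)
from podtree.tree import classify_table, evaluate


def random_instance(seed, ncue=4, nmax=30, binary=True):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, nmax + 1))
    while True:
        X = rng.integers(0, 2 if binary else 5, size=(n, ncue))
        y = rng.integers(0, 2, size=n)
        if 0 < y.sum() < n:
            break
    cols = {f"c{j}": X[:, j] for j in range(ncue)}
    table = make_table(cols, y)
    rows = [{k: float(v[i]) for k, v in cols.items()} for i in range(n)]
    return table, rows, y.tolist()


class TestBestSplit:
    def test_perfectly_separable(self):
        s = best_split_for_cue([1, 2, 3, 4], [0, 0, 1, 1], cue="x")
        assert (s.rule.direction, s.rule.threshold) == (">", 2)
        assert s.goal == 1.0

    def test_constant_column_goal_is_half(self):
        s = best_split_for_cue([3, 3, 3, 3], [0, 1, 0, 1], cue="x")
        assert s.goal == 0.5
        assert s.sens == 1.0  # tie resolved toward higher sensitivity

    def test_single_class_is_fatal(self):
        with pytest.raises(ValueError, match="single class"):
            best_split_for_cue([1, 2, 3], [1, 1, 1], cue="x")

    def test_missing_values_are_fatal(self):
        with pytest.raises(ValueError, match="impute"):
            best_split_for_cue([1.0, np.nan], [0, 1], cue="x")

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, size=30).astype(float)
        labels = rng.integers(0, 2, size=30)
        if not 0 < labels.sum() < 30:
            labels[0] = 1 - labels[0]
        s = best_split_for_cue(values, labels, cue="x")
        direction, threshold, goal, sens = naive_best_rule(values.tolist(),
                                                           labels.tolist())
        assert s.goal == pytest.approx(goal, abs=1e-12)
        assert (s.rule.direction, s.rule.threshold) == (direction, threshold)
        assert s.sens == pytest.approx(sens, abs=1e-12)


class TestRankCues:
    def test_perfect_cue_ranks_first(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=40)
        table = make_table({"noise1": rng.integers(0, 3, 40),
                            "perfect": y,
                            "noise2": rng.integers(0, 3, 40)}, y)
        ranked = rank_cues(table)
        assert ranked[0].cue == "perfect"
        assert ranked[0].goal == 1.0

    def test_identical_columns_tie_alphabetically(self):
        y = [0, 1, 0, 1, 1, 0]
        col = [0, 1, 0, 1, 1, 0]
        table = make_table({"zeta": col, "alpha": col}, y)
        ranked = rank_cues(table)
        assert [s.cue for s in ranked] == ["alpha", "zeta"]

    @pytest.mark.parametrize("seed", range(5))
    def test_order_matches_per_cue_brute_force(self, seed):
        table, rows, labels = random_instance(seed, ncue=5, nmax=40, binary=False)
        ranked = rank_cues(table)
        naive = []
        for cue in sorted(rows[0]):
            values = [r[cue] for r in rows]
            direction, threshold, goal, sens = naive_best_rule(values, labels)
            naive.append(((-goal, -sens, threshold,
                           0 if direction == ">" else 1, cue), cue))
        naive.sort()
        assert [s.cue for s in ranked] == [c for _, c in naive]


class TestIfan:
    def test_single_perfect_cue_gives_depth_one(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=30)
        table = make_table({"perfect": y, "noise": rng.integers(0, 2, 30)}, y)
        tree = build_ifan(table)
        assert tree.depth == 1
        assert tree.goal_value == 1.0

    def test_fan_has_complete_exit_structures(self):
        table, _, _ = random_instance(3, ncue=4)
        results = FastFrugalTreeModel(table, "ifan", max_levels=4).fit()
        counts = results.fan_.groupby("depth").size()
        assert counts.to_dict() == {1: 1, 2: 2, 3: 4, 4: 8}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_prefix_search(self, seed):
        table, rows, labels = random_instance(seed)
        tree = build_ifan(table, max_levels=3)
        assert evaluate(tree, table).bacc == pytest.approx(
            ifan_oracle_goal(rows, labels, max_levels=3), abs=1e-12)

    def test_recovers_planted_tree_exactly(self):
        table = generate_planted(default_planted_config(2000, 0.0, seed=0))
        tree = build_ifan(table)
        assert tree.nodes == default_planted_tree().nodes
        assert tree.goal_value == 1.0

    def test_adding_perfect_cue_never_hurts(self):
        table, _, labels = random_instance(7, ncue=3)
        before = build_ifan(table).goal_value
        richer = table.data.copy()
        richer.insert(0, "oracle_cue", np.asarray(labels, dtype=float))
        from podtree import CohortTable
        after = build_ifan(CohortTable(richer)).goal_value
        assert after >= before
        assert after == 1.0

    def test_max_levels_below_one_is_fatal(self):
        table, _, _ = random_instance(0)
        with pytest.raises(ValueError):
            build_ifan(table, max_levels=0)


class TestDfan:
    def test_truncates_on_no_improvement(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=30)
        table = make_table({"perfect": y, "n1": rng.integers(0, 2, 30),
                            "n2": rng.integers(0, 2, 30)}, y)
        tree = build_dfan(table, max_levels=4)
        assert tree.depth == 1
        assert tree.goal_value == 1.0

    def test_truncates_planted_three_cue_tree_below_depth_cap(self):
        table = generate_planted(default_planted_config(2000, 0.0, seed=0))
        tree = build_dfan(table, max_levels=4)
        assert tree.depth == 3
        assert tree.nodes == default_planted_tree().nodes

    def test_conditional_reranking_beats_fixed_marginal_order(self):
        # duplicated strong cue: ifan's marginal ranking wastes its two top
        # slots on the same information; dfan re-ranks conditionally and finds
        # the complementary weaker cue
        b = [1] * 6 + [0] * 10
        y = [1] * 6 + [1] * 4 + [0] * 6
        a = [0] * 6 + [1] * 4 + [0] * 6
        table = make_table({"b_strong": b, "c_duplicate": b, "a_weak": a}, y)
        ifan_goal = evaluate(build_ifan(table, max_levels=2), table).bacc
        dfan_goal = evaluate(build_dfan(table, max_levels=2), table).bacc
        assert dfan_goal >= ifan_goal
        assert dfan_goal == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_reimplementation(self, seed):
        table, rows, labels = random_instance(seed)
        tree = build_dfan(table, max_levels=3)
        assert evaluate(tree, table).bacc == pytest.approx(
            dfan_greedy_goal(rows, labels, max_levels=3), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_never_exceeds_all_orders_bound(self, seed):
        table, rows, labels = random_instance(seed, ncue=3)
        tree = build_dfan(table, max_levels=3)
        bound = dfan_oracle_goal(rows, labels, max_levels=3)
        assert evaluate(tree, table).bacc <= bound + 1e-12


class TestModelSurface:
    def test_results_carry_training_fit_and_summary(self, table1_cohort):
        results = FastFrugalTreeModel(table1_cohort, "ifan").fit()
        assert results.tree.depth <= 5
        assert results.train_perf.bacc == results.tree.goal_value
        text = results.summary()
        assert "ifan" in text and "bacc" in text

    def test_predict_matches_classify_table(self, table1_cohort):
        results = FastFrugalTreeModel(table1_cohort, "ifan").fit()
        expected, _ = classify_table(results.tree, table1_cohort.cue_frame)
        np.testing.assert_array_equal(results.predict(table1_cohort),
                                      expected.astype(int))

    def test_from_dataframe_round_trip(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.integers(0, 3, 40).astype(float),
                           "outcome": rng.integers(0, 2, 40)})
        model = FastFrugalTreeModel.from_dataframe(df, outcome="outcome")
        assert model.cohort.n == 40

    def test_unknown_algorithm_rejected(self, table1_cohort):
        with pytest.raises(ValueError):
            FastFrugalTreeModel(table1_cohort, "xfan")
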