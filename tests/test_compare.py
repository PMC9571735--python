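"""Paired-split comparison harness: pairing, aggregation, win rates."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from podtree import (ComparisonResult, FastFrugalTreeModel, GeneratorConfig,
                     ModelSpec, PerfStats, aggregate, generate_cohort,
                     run_comparison, win_rate)
from podtree.compare import TrialRecord, split_fingerprint, trial_seed
from podtree.cohort import split_half


def perfect_cue_table(n=40):
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=n)
    while not 0 < y.sum() < n:
        y = rng.integers(0, 2, size=n)
    return make_table({"perfect": y, "noise": rng.integers(0, 2, n)}, y)


def fake_result(baccs_a, baccs_b):
    """Hand-built two-model ComparisonResult with given test baccs."""
    def stats(bacc):
        k = int(round(bacc * 10))
        return PerfStats(hi=k, mi=10 - k, fa=10 - k, cr=k)

    trials = []
    for i, (a, b) in enumerate(zip(baccs_a, baccs_b)):
        t = TrialRecord(trial_id=i, seed=i, fingerprint=str(i))
        t.perf["A"] = {"train": stats(a), "test": stats(a)}
        t.perf["B"] = {"train": stats(b), "test": stats(b)}
        trials.append(t)
    return ComparisonResult(trials, ["A", "B"], len(trials), len(trials), 0)


class TestRunComparison:
    def test_single_trial_perfect_cue(self):
        models = [ModelSpec("FFTi", lambda t: FastFrugalTreeModel(t, "ifan").fit())]
        result = run_comparison(perfect_cue_table(), models, n_trials_fast=1,
                                n_trials_slow=1, master_seed=0)
        perf = result.trials[0].perf["FFTi"]
        assert perf["train"].bacc == 1.0
        assert perf["test"].bacc == 1.0

    def test_rerun_is_bit_identical(self):
        table = generate_cohort(GeneratorConfig(n=60, seed=1))
        models = [ModelSpec("FFTi", lambda t: FastFrugalTreeModel(t, "ifan").fit()),
                  ModelSpec("FFTd", lambda t: FastFrugalTreeModel(t, "dfan").fit())]
        r1 = run_comparison(table, models, n_trials_fast=3, n_trials_slow=3,
                            master_seed=7)
        r2 = run_comparison(table, models, n_trials_fast=3, n_trials_slow=3,
                            master_seed=7)
        pd.testing.assert_frame_equal(r1.to_tidy(), r2.to_tidy())
        assert [t.fingerprint for t in r1.trials] == [t.fingerprint for t in r2.trials]

    def test_trial_splits_are_reproducible_in_isolation(self):
        table = generate_cohort(GeneratorConfig(n=60, seed=1))
        models = [ModelSpec("FFTi", lambda t: FastFrugalTreeModel(t, "ifan").fit())]
        result = run_comparison(table, models, n_trials_fast=4, n_trials_slow=4,
                                master_seed=11)
        for t in result.trials:
            assert t.seed == trial_seed(11, t.trial_id)
            assert split_fingerprint(split_half(table, t.seed)) == t.fingerprint

    def test_slow_models_restricted_to_first_trials(self):
        table = generate_cohort(GeneratorConfig(n=60, seed=1))
        models = [ModelSpec("fast", lambda t: FastFrugalTreeModel(t, "ifan").fit()),
                  ModelSpec("slow", lambda t: FastFrugalTreeModel(t, "ifan").fit(),
                            slow=True)]
        result = run_comparison(table, models, n_trials_fast=5, n_trials_slow=2,
                                master_seed=0)
        assert ["slow" in t.perf for t in result.trials] == [True, True, False,
                                                             False, False]

    def test_unimputed_cohort_is_fatal(self):
        from podtree import inject_missing
        table = inject_missing(generate_cohort(GeneratorConfig(n=60, seed=1)), 0.2)
        with pytest.raises(ValueError, match="impute"):
            run_comparison(table, n_trials_fast=1, n_trials_slow=1)

    def test_always_failing_model_aborts_with_diagnostics(self):
        def broken(train):
            raise RuntimeError("boom")

        models = [ModelSpec("broken", broken)]
        with pytest.raises(RuntimeError, match="broken.*boom"):
            run_comparison(perfect_cue_table(), models, n_trials_fast=5,
                           n_trials_slow=5, master_seed=0)

    def test_rare_failure_is_recorded_and_skipped(self):
        calls = {"n": 0}

        class Fitted:
            def __init__(self, train):
                self.inner = FastFrugalTreeModel(train, "ifan").fit()

            def evaluate(self, table):
                return self.inner.evaluate(table)

        def flaky(train):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("transient")
            return Fitted(train)

        table = generate_cohort(GeneratorConfig(n=60, seed=1))
        result = run_comparison(table, [ModelSpec("flaky", flaky)],
                                n_trials_fast=150, n_trials_slow=150, master_seed=0)
        assert "flaky" in result.trials[0].failures
        assert "flaky" not in result.trials[0].perf
        assert all("flaky" in t.perf for t in result.trials[1:])


class TestAggregate:
    def test_two_point_mean_and_standard_error(self):
        result = fake_result([0.6, 0.8], [0.7, 0.7])
        agg = aggregate(result)
        assert agg.loc[("A", "test"), "bacc_mean"] == pytest.approx(0.7)
        assert agg.loc[("A", "test"), "bacc_se"] == pytest.approx(0.1)

    def test_constant_values_have_zero_standard_error(self):
        result = fake_result([0.6, 0.6, 0.6], [0.7, 0.7, 0.7])
        agg = aggregate(result)
        assert agg.loc[("B", "train"), "bacc_se"] == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        baccs = np.round(rng.uniform(0.1, 0.9, size=100), 1)
        result = fake_result(baccs, baccs[::-1])
        agg = aggregate(result)
        assert agg.loc[("A", "test"), "bacc_mean"] == pytest.approx(baccs.mean())
        assert agg.loc[("A", "test"), "bacc_se"] == pytest.approx(
            baccs.std(ddof=1) / np.sqrt(100))

    def test_fewer_than_two_trials_is_fatal(self):
        result = fake_result([0.6], [0.7])
        with pytest.raises(ValueError):
            aggregate(result)


class TestWinRate:
    def test_hand_counted_example(self):
        result = fake_result([0.7, 0.6, 0.5], [0.6, 0.6, 0.6])
        assert win_rate(result, "A", "B") == pytest.approx(1 / 3)
        assert win_rate(result, "B", "A") == pytest.approx(1 / 3)

    def test_model_never_beats_itself(self):
        result = fake_result([0.7, 0.6], [0.5, 0.5])
        assert win_rate(result, "A", "A") == 0.0

    def test_win_matrix_diagonal_zero_and_sums_below_one(self):
        rng = np.random.default_rng(5)
        result = fake_result(np.round(rng.uniform(0.2, 0.8, 50), 1),
                             np.round(rng.uniform(0.2, 0.8, 50), 1))
        m = result.win_matrix()
        assert (np.diag(m) == 0).all()
        assert m.loc["A", "B"] + m.loc["B", "A"] <= 1.0

    def test_no_common_trials_is_fatal(self):
        result = fake_result([0.6, 0.7], [0.5, 0.5])
        result.trials[0].perf.pop("B")
        result.trials[1].perf.pop("B")
        with pytest.raises(ValueError, match="share no trials"):
            win_rate(result, "A", "B")
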