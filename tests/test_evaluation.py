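"""Resampling protocol, performance metrics, chance tests and relevance
aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emohex.angle_glvq import TrainingConfig
from emohex.errors import (
    EmptyAggregateError,
    StratificationError,
    UndefinedMetricError,
    ValidationError,
    ZeroVarianceError,
)
from emohex.evaluation import (
    TASKS,
    RunResult,
    aggregate_relevance,
    binomial_chance_test,
    confusion_counts,
    kruskal_wallis,
    macro_accuracy,
    predictive_values,
    run_task,
    split_resample,
    summarize_runs,
)


class TestSplitResample:
    def test_balanced_75_25(self):
        y = np.array(["A"] * 50 + ["B"] * 50)
        splits = split_resample(y, 10, 0.75, master_seed=0)
        assert len(splits) == 10
        for tr, te in splits:
            # per-class training count = round-half-up(50 * 0.75) = 38
            assert len(tr) == 76 and len(te) == 24
            assert (np.sort(np.concatenate([tr, te])) == np.arange(100)).all()
            assert (y[tr] == "A").sum() == 38
            assert (y[te] == "A").sum() == 12

    def test_round_half_up_for_class_of_four(self):
        y = np.array(["A"] * 4 + ["B"] * 8)
        tr, te = split_resample(y, 1, 0.75, master_seed=1)[0]
        assert (y[tr] == "A").sum() == 3
        assert (y[te] == "A").sum() == 1

    def test_seeded_determinism(self):
        y = np.array(["A"] * 20 + ["B"] * 20)
        a = split_resample(y, 5, 0.75, master_seed=3)
        b = split_resample(y, 5, 0.75, master_seed=3)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_too_small_class_rejected(self):
        y = np.array(["A"] * 1 + ["B"] * 10)
        with pytest.raises(StratificationError):
            split_resample(y, 1, 0.75, master_seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            split_resample(np.array(["A", "A", "B", "B"]), 1, 1.0)


class TestMetrics:
    def test_perfect_confusion(self):
        assert macro_accuracy(10, 0, 20, 0) == 1.0

    def test_printed_table_style_counts(self):
        assert macro_accuracy(54, 25, 75, 46) == pytest.approx(0.645)

    def test_all_predicted_negative_is_half(self):
        assert macro_accuracy(0, 0, 30, 10) == pytest.approx(0.5)

    def test_empty_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            macro_accuracy(0, 5, 5, 0)

    def test_predictive_values_direct_arithmetic(self):
        pv = predictive_values(54, 25, 75, 46)
        assert pv["ppv"] == pytest.approx(54 / 79)
        assert pv["npv"] == pytest.approx(75 / 121)
        assert pv["tpr"] == pytest.approx(54 / 100)
        assert pv["tnr"] == pytest.approx(75 / 100)

    def test_no_positive_predictions_flags_ppv_missing(self):
        pv = predictive_values(0, 0, 30, 10)
        assert pv["ppv"] is None
        assert pv["npv"] == pytest.approx(30 / 40)

    def test_confusion_counts_reconcile(self):
        y = np.array(["P", "P", "N", "N", "P"])
        p = np.array(["P", "N", "N", "P", "P"])
        tp, fp, tn, fn = confusion_counts(y, p, "P", "N")
        assert (tp, fp, tn, fn) == (2, 1, 1, 1)
        assert tp + fn == (y == "P").sum()
        assert tn + fp == (y == "N").sum()


class TestBinomialChanceTest:
    def test_all_correct_of_ten(self):
        assert binomial_chance_test(10, 10) == pytest.approx(2 * 0.5**10)

    def test_observation_at_the_mode(self):
        assert binomial_chance_test(5, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_tail_sum(self):
        # two-sided exact: sum of P(k) over all k no more likely than observed
        n, k = 100, 60
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        expected = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
        assert binomial_chance_test(k, n) == pytest.approx(expected, abs=1e-12)
        assert binomial_chance_test(k, n) == pytest.approx(0.0569, abs=5e-4)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            binomial_chance_test(5, 0)
        with pytest.raises(ValidationError):
            binomial_chance_test(-1, 10)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_two_identical_groups_give_zero(self):
        h, _ = kruskal_wallis([[1.0, 2.0], [1.0, 2.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_observations_rejected(self):
        with pytest.raises(ZeroVarianceError):
            kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])

    def test_matches_rank_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            groups = [rng.normal(size=rng.integers(4, 12)) for _ in range(3)]
            flat = np.concatenate(groups)
            ranks = stats.rankdata(flat)
            n = len(flat)
            h = 0.0
            start = 0
            for g in groups:
                r = ranks[start : start + len(g)]
                h += len(g) * (r.mean() - (n + 1) / 2) ** 2
                start += len(g)
            h *= 12 / (n * (n + 1))
            # tie correction (continuous data: factor 1, but apply anyway)
            _, counts = np.unique(flat, return_counts=True)
            h /= 1 - ((counts**3 - counts).sum() / (n**3 - n))
            assert kruskal_wallis(groups)[0] == pytest.approx(h, abs=1e-8)


def synthetic_features(n_pos, n_neg, shift, seed, groups=("HCU", "TD")):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(shift, 1, (n_pos, 12)), rng.normal(0, 1, (n_neg, 12))]
    )
    pids = [f"P{i:04d}" for i in range(n_pos + n_neg)]
    feats = pd.DataFrame(X, index=pids, columns=[f"f{j}" for j in range(12)])
    parts = pd.DataFrame(
        {"participant_id": pids, "group": [groups[0]] * n_pos + [groups[1]] * n_neg}
    )
    return feats, parts


class TestRunTask:
    def test_produces_one_result_per_repeat_and_counts_reconcile(self):
        feats, parts = synthetic_features(20, 40, 0.0, seed=1)
        runs = run_task(
            feats, parts, TASKS["HCU-TD"],
            config=TrainingConfig(epochs=30), n_repeats=7, master_seed=2,
        )
        assert len(runs) == 7
        for r in runs:
            assert r.tp + r.fn == 5  # 25% of 20 positives held out
            assert r.tn + r.fp == 10
            assert r.macro_accuracy == pytest.approx(
                macro_accuracy(r.tp, r.fp, r.tn, r.fn)
            )
            assert r.relevance.sum() == pytest.approx(1.0, abs=1e-10)

    def test_large_injected_deficit_classifies_well(self):
        # HCU shifted -1 SD on all 12 features; the angle metric sees only
        # the direction change, which still supports clearly above-chance
        # discrimination
        feats, parts = synthetic_features(80, 240, -1.0, seed=0)
        runs = run_task(feats, parts, TASKS["HCU-TD"], n_repeats=100, master_seed=0)
        assert np.mean([r.macro_accuracy for r in runs]) > 0.7

    def test_missing_group_surfaces_task_name(self):
        feats, parts = synthetic_features(15, 30, 0.0, seed=3, groups=("LCU", "TD"))
        with pytest.raises(StratificationError, match="HCU-TD"):
            run_task(feats, parts, TASKS["HCU-TD"], n_repeats=2)

    def test_cd_td_task_merges_subtypes(self):
        assert TASKS["CD-TD"].mapping == {"HCU": "CD", "LCU": "CD", "TD": "TD"}
        groups = pd.Series(["HCU", "LCU", "TD"])
        assert list(TASKS["CD-TD"].classes(groups)) == ["CD", "CD", "TD"]

    def test_summary_table_and_pooled_binomial(self):
        feats, parts = synthetic_features(20, 40, -1.5, seed=4)
        runs = run_task(
            feats, parts, TASKS["HCU-TD"],
            config=TrainingConfig(epochs=50), n_repeats=10, master_seed=5,
        )
        summary = summarize_runs(runs)
        assert set(summary["metric"]) == {"macro_accuracy", "ppv", "npv", "tpr", "tnr"}
        row = summary.set_index("metric").loc["macro_accuracy"]
        assert row["ci95_low"] <= row["mean"] <= row["ci95_high"]
        assert summary.attrs["pooled_total"] == 10 * 15
        assert 0.0 <= summary.attrs["binomial_p_vs_chance"] <= 1.0


class TestAggregateRelevance:
    @staticmethod
    def run_with(acc, rel):
        return RunResult(0, 0, 1, 1, 1, 1, acc, None, None, None, None,
                         np.asarray(rel))

    def test_threshold_filtering(self):
        runs = [
            self.run_with(0.45, [0.5, 0.5]),
            self.run_with(0.55, [0.6, 0.4]),
            self.run_with(0.60, [0.2, 0.8]),
        ]
        agg = aggregate_relevance(runs, threshold=0.5)
        assert agg.retained == 2
        np.testing.assert_allclose(agg.mean_relevance, [0.4, 0.6])
        assert agg.mean_relevance.sum() == pytest.approx(1.0, abs=1e-8)

    def test_all_runs_below_threshold_rejected(self):
        runs = [self.run_with(0.30, [0.5, 0.5])]
        with pytest.raises(EmptyAggregateError):
            aggregate_relevance(runs, threshold=0.5)

    def test_stricter_discussion_threshold_supported(self):
        runs = [self.run_with(0.55, [0.5, 0.5]), self.run_with(0.65, [0.3, 0.7])]
        agg = aggregate_relevance(runs, threshold=0.6)
        assert agg.retained == 1
        np.testing.assert_allclose(agg.mean_relevance, [0.3, 0.7])


def test_fear_specific_signal_tops_relevance_ranking():
    """Lowering only high-intensity fear recognition for the HCU group makes
    fear_high the top mean-relevance feature of the HCU-TD comparison."""
    from emohex import hexagon, residualize, synthetic

    hits = 0
    n_seeds = 4
    for ms in range(n_seeds):
        p = synthetic.default_p_correct()
        p = {k: (0.55 if k == ("HCU", "fear", "high") else v) for k, v in p.items()}
        spec = synthetic.CohortSpec(
            group_sizes={"HCU": 80, "LCU": 0, "TD": 160},
            p_correct=p, reps_per_blend=10, seed=ms,
        )
        parts = synthetic.generate_participants(spec)
        trials = synthetic.generate_trials(parts, spec)
        feats = hexagon.accuracy_features(trials)
        design = residualize.build_design(
            parts.set_index("participant_id").loc[feats.index].reset_index()
        )
        res = residualize.residualize_features(feats, design)
        runs = run_task(
            res, parts, TASKS["HCU-TD"],
            config=TrainingConfig(epochs=1000, lr_decay=0.999),
            n_repeats=10, master_seed=ms,
        )
        agg = aggregate_relevance(runs, feature_names=tuple(res.columns))
        hits += res.columns[int(np.argmax(agg.mean_relevance))] == "fear_high"
    assert hits >= 0.8 * n_seeds
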