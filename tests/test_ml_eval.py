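import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conswat.ml_eval import (
    CRITERIA,
    FAMILIES,
    CombinationReport,
    ConfusionCounts,
    MetricSet,
    ModelSpec,
    auc_score,
    average_metrics,
    best_model,
    compare_models,
    compute_metrics,
    confusion_counts,
    enumerate_combinations,
    evaluate_combinations,
    five_fold_cv,
    load_artifact,
    predict,
    rank_combinations,
    select_best_combination,
    train_final,
)


def _separable_table(n=60, seed=0):
    """A deterministically separable rule: CWM iff A > 0."""
    rng = np.random.default_rng(seed)
    a = np.concatenate([rng.uniform(1, 2, n // 2), rng.uniform(-2, -1, n - n // 2)])
    df = pd.DataFrame({"A": a, "B": rng.normal(size=n), "C": rng.normal(size=n)})
    df["label"] = np.where(df["A"] > 0, "CWM", "FWM")
    return df


class TestConfusionAndMetrics:
    def test_hand_counted_confusion(self):
        got = confusion_counts(["CWM", "CWM", "FWM"], ["CWM", "FWM", "FWM"])
        assert (got.tp, got.fp, got.tn, got.fn) == (1, 0, 1, 1)

    def test_perfect_and_inverted_predictions(self):
        y = ["CWM", "FWM", "CWM", "FWM"]
        perfect = confusion_counts(y, y)
        assert perfect.fp == perfect.fn == 0
        flipped = confusion_counts(y, ["FWM", "CWM", "FWM", "CWM"])
        assert flipped.tp == flipped.tn == 0

    def test_length_mismatch_and_unknown_labels_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(["CWM"], ["CWM", "FWM"])
        with pytest.raises(ValueError, match="unknown label"):
            confusion_counts(["CWM"], ["maybe"])

    def test_metric_formulas_on_known_counts(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m.acc == pytest.approx(0.7)
        assert m.sn == pytest.approx(0.6)
        assert m.ppv == pytest.approx(0.75)
        assert m.fscore == pytest.approx(6 / 9)

    def test_perfect_prediction_and_separated_scores(self):
        m = compute_metrics(
            ConfusionCounts(5, 0, 5, 0),
            truth=["CWM"] * 5 + ["FWM"] * 5,
            scores=[0.9] * 5 + [0.1] * 5,
        )
        assert (m.acc, m.sn, m.ppv, m.fscore, m.auc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_ratios_are_absent_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m.ppv is None and m.sn is None and m.acc == 1.0
        assert auc_score(["FWM", "FWM"], [0.1, 0.2]) is None

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_metric_identities(self, tp, fp, tn, fn):
        counts = ConfusionCounts(tp, fp, tn, fn)
        if counts.n == 0:
            return
        m = compute_metrics(counts)
        assert m.acc * counts.n == pytest.approx(tp + tn)
        if m.sn is not None and m.ppv is not None and (m.sn + m.ppv) > 0:
            assert m.fscore == pytest.approx(2 * m.ppv * m.sn / (m.ppv + m.sn))
        for v in (m.acc, m.sn, m.ppv, m.fscore):
            assert v is None or 0.0 <= v <= 1.0

    def test_auc_equals_brute_force_pairwise_probability(self):
        rng = np.random.default_rng(12)
        truth = ["CWM" if b else "FWM" for b in rng.integers(0, 2, 150)]
        scores = np.round(rng.uniform(0, 1, 150), 2)  # rounding forces ties
        pos = [s for t, s in zip(truth, scores) if t == "CWM"]
        neg = [s for t, s in zip(truth, scores) if t == "FWM"]
        wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert auc_score(truth, scores) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestCrossValidation:
    def test_separable_rule_gives_perfect_pooled_accuracy(self):
        df = _separable_table()
        m = five_fold_cv(df, ModelSpec("DT", seed=0), letters="ABC", seed=0)
        assert m.acc == 1.0

    def test_deterministic_under_repetition(self, small_feature_table):
        spec = ModelSpec("EL", seed=3)
        a = five_fold_cv(small_feature_table, spec, seed=3)
        b = five_fold_cv(small_feature_table, spec, seed=3)
        assert a == b

    def test_pooled_metrics_invariant_to_row_order(self, small_feature_table):
        spec = ModelSpec("KNN", seed=3)
        a = five_fold_cv(small_feature_table, spec, seed=3)
        shuffled = small_feature_table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        b = five_fold_cv(shuffled, spec, seed=3)
        assert a == b

    def test_class_with_too_few_rows_errors(self):
        df = _separable_table(n=20)
        df = pd.concat([df[df.label == "CWM"], df[df.label == "FWM"].head(3)])
        with pytest.raises(ValueError, match="at least 5"):
            five_fold_cv(df, ModelSpec("DT"), letters="ABC")


class TestCombinations:
    def test_six_features_give_63_ordered_subsets(self):
        combos = enumerate_combinations("ABCDEF")
        assert len(combos) == 63
        assert combos[0] == "ABCDEF"
        assert combos[-1] == "F"
        assert combos[1:7] == ["ABCDE", "ABCDF", "ABCEF", "ABDEF", "ACDEF", "BCDEF"]

    @given(k=st.integers(1, 8))
    def test_subset_count_is_two_to_k_minus_one(self, k):
        letters = "ABCDEFGH"[:k]
        combos = enumerate_combinations(letters)
        assert len(combos) == 2**k - 1
        assert len(set(combos)) == len(combos)

    def test_empty_feature_set_errors(self):
        with pytest.raises(ValueError):
            enumerate_combinations("")

    def test_evaluate_reports_average_of_per_model_values(self, small_feature_table):
        reports = evaluate_combinations(
            small_feature_table, seed=2, letters="AF", families=("DT", "NB", "KNN")
        )
        assert len(reports) == 3  # AF, A, F
        for r in reports:
            assert set(r.per_model) == {"DT", "NB", "KNN"}
            for c in CRITERIA:
                vals = [m.as_dict()[c] for m in r.per_model.values()]
                assert r.averaged.as_dict()[c] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_signal_features_beat_noise_feature(self, small_feature_table):
        """A combination of class-separating features outperforms the weakest
        single feature by a clear margin."""
        reports = {
            r.combination: r
            for r in evaluate_combinations(small_feature_table, seed=2, letters="AC", families=("DT", "NB"))
        }
        assert reports["AC"].averaged.acc >= reports["C"].averaged.acc - 0.05


class TestRanking:
    def test_tolerance_band_ties(self):
        reports = [
            CombinationReport.from_averaged("ABCDEF", acc=0.725),
            CombinationReport.from_averaged("BCDEF", acc=0.724),
            CombinationReport.from_averaged("ABCF", acc=0.720),
        ]
        assert rank_combinations(reports, "acc", 0.001) == ["ABCDEF", "BCDEF"]
        assert rank_combinations(reports, "acc", 0.0) == ["ABCDEF"]

    def test_winner_counts_criteria_with_tie_break(self):
        reports = [
            CombinationReport.from_averaged("AB", acc=0.9, sn=0.5, ppv=0.9, fscore=0.9, auc=0.9),
            CombinationReport.from_averaged("A", acc=0.8, sn=0.9, ppv=0.8, fscore=0.8, auc=0.8),
        ]
        winner, best_sets = select_best_combination(reports, tolerance=0.0)
        assert winner == "AB"
        assert best_sets["sn"] == ["A"]


class TestModelComparison:
    def test_constant_criteria_average_to_the_constant(self):
        m = MetricSet(acc=0.8, sn=0.8, ppv=0.8, fscore=0.8, auc=0.8)
        assert m.average_performance() == pytest.approx(0.8)

    def test_compare_reports_all_families_and_average(self, small_feature_table):
        table = compare_models(small_feature_table, combination="AF", seed=2, families=("DT", "EL"))
        assert list(table["model"]) == ["DT", "EL"]
        for _, row in table.iterrows():
            assert row["average_performance"] == pytest.approx(
                np.mean([row[c] for c in CRITERIA])
            )


class TestPublishedBenchmarks:
    """Internal-consistency checks on the published benchmark tables."""

    def test_fscore_is_harmonic_mean_of_printed_sn_and_ppv(self, benchmark_model_metrics):
        for _, row in benchmark_model_metrics.iterrows():
            f = 2 * row.ppv * row.sn / (row.ppv + row.sn)
            assert round(f, 3) == pytest.approx(row.fscore, abs=1e-9), row.model

    def test_average_performance_is_mean_of_printed_criteria(self, benchmark_model_metrics):
        for _, row in benchmark_model_metrics.iterrows():
            avg = np.mean([row[c] for c in CRITERIA])
            assert round(avg, 3) == pytest.approx(row.average_performance, abs=1e-9), row.model

    def test_ensemble_is_the_best_published_model(self, benchmark_model_metrics):
        assert best_model(benchmark_model_metrics) == "EL"

    def test_full_combination_wins_four_of_five_criteria(self, benchmark_combination_averages):
        reports = [
            CombinationReport.from_averaged(row.combination, **{c: getattr(row, c) for c in CRITERIA})
            for row in benchmark_combination_averages.itertuples()
        ]
        winner, best_sets = select_best_combination(reports, tolerance=0.001)
        assert winner == "ABCDEF"
        n_won = sum("ABCDEF" in combos for combos in best_sets.values())
        assert n_won == 4
        assert best_sets["sn"] == ["A"]  # atom density alone maximises sensitivity
        assert set(best_sets["acc"]) == {"ABCDEF", "BCDEF", "ABCF"}


class TestFinalModel:
    def test_artifact_round_trip_predicts_identically(self, small_feature_table, tmp_path):
        path = tmp_path / "model.joblib"
        artifact = train_final(small_feature_table, ModelSpec("EL", seed=1), "ABCDEF", path=path)
        loaded = load_artifact(path)
        a = predict(artifact, small_feature_table)
        b = predict(loaded, small_feature_table)
        pd.testing.assert_frame_equal(a, b)

    def test_training_accuracy_perfect_on_separable_rule(self):
        df = _separable_table()
        artifact = train_final(df, ModelSpec("DT", seed=0), "ABC")
        out = predict(artifact, df)
        assert (out["predicted_label"] == df["label"]).all()

    def test_stale_artifact_version_rejected(self, small_feature_table, tmp_path):
        import joblib

        path = tmp_path / "old.joblib"
        artifact = train_final(small_feature_table, ModelSpec("DT", seed=1), "AB", path=path)
        artifact["format_version"] = 99
        joblib.dump(artifact, path)
        with pytest.raises(ValueError, match="version"):
            load_artifact(path)

    def test_score_threshold_reproduces_labels(self, small_feature_table):
        artifact = train_final(small_feature_table, ModelSpec("EL", seed=1), "ABCDEF")
        out = predict(artifact, small_feature_table)
        thresholded = np.where(out["score"] >= 0.5, "CWM", "FWM")
        assert (thresholded == out["predicted_label"]).all()

    def test_identical_rows_get_identical_predictions(self, small_feature_table):
        artifact = train_final(small_feature_table, ModelSpec("EL", seed=1), "ABCDEF")
        row = small_feature_table.head(1)
        dup = pd.concat([row] * 5, ignore_index=True)
        out = predict(artifact, dup)
        assert out["predicted_label"].nunique() == 1
        assert out["score"].nunique() == 1

    def test_missing_feature_column_errors(self, small_feature_table):
        artifact = train_final(small_feature_table, ModelSpec("DT", seed=1), "ABCDEF")
        with pytest.raises(KeyError, match="missing"):
            predict(artifact, small_feature_table.drop(columns=["C"]))

    def test_nan_feature_errors(self, small_feature_table):
        artifact = train_final(small_feature_table, ModelSpec("DT", seed=1), "AB")
        broken = small_feature_table.copy()
        broken.loc[0, "A"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            predict(artifact, broken)
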