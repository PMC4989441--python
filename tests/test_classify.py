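"""Feature construction, learned metric, NN classification, evaluation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_feature_problem

from cardiostate.classify import (
    ATTRIBUTE_SUBSETS,
    DistanceMetric,
    FeatureTable,
    OPTIMAL12,
    SubjectAnalysis,
    attribute_cascade,
    build_features,
    distance,
    evaluate_holdout,
    evaluate_loocv,
    learn_metric,
    nn_classify,
)
from cardiostate.coherence import CoherenceSpectrum
from cardiostate.errors import (
    ClassTooSmall,
    DimensionMismatch,
    EmptyTrainingSet,
    MissingAnalysis,
)
from cardiostate.sync import SyncResult
from cardiostate.timefreq import BandEnergyTable


def _analysis(subject="s1", state="awake", drop_channel=None):
    bands = {
        "hrv": BandEnergyTable({"II": 0.1, "III": 0.2, "IV": 0.15, "V": 0.1}, 0.55, "hrv"),
        "rfv": BandEnergyTable({"III": 0.02, "IV": 0.02, "V": 0.01}, 0.05, "rfv"),
        "scond": BandEnergyTable({"III": 0.3, "IV": 0.2, "V": 0.2, "VI": 0.1}, 0.8, "scond"),
        "temp": BandEnergyTable({"III": 0.01, "IV": 0.01, "V": 0.02, "VI": 0.02}, 0.06, "temp"),
    }
    if drop_channel:
        bands.pop(drop_channel)
    freqs = np.logspace(np.log10(0.005), np.log10(2.0), 60)
    coh = {
        key: CoherenceSpectrum(freqs=freqs, coherence=np.full(60, 0.6))
        for key in ("hrv_scond", "hrv_pulse", "hrv_temp", "scond_pulse", "scond_temp", "pulse_temp")
    }
    sync = SyncResult(
        traces=[], T=4.0, window_1n=24.0, window_2n=32.0,
        total_sync_time=120.0, duration=600.0,
    )
    return SubjectAnalysis(
        subject_id=subject, state=state,
        mean_heart_rate=1.07, mean_resp_rate=0.22, mean_temperature=30.0,
        mean_conductivity=2.0, mean_ptt=0.18,
        band_energy=bands, coherence=coh, sync=sync,
    )


class TestBuildFeatures:
    def test_optimal12_has_exactly_the_twelve_attributes(self):
        vec = build_features(_analysis(), subset="optimal12")
        assert list(vec.index) == OPTIMAL12
        assert len(vec) == 12

    def test_missing_channel_names_absent_attribute(self):
        with pytest.raises(MissingAnalysis, match="scond_energy_VI"):
            build_features(_analysis(drop_channel="scond"), subset="optimal12")

    def test_identical_analyses_give_identical_vectors(self):
        v1 = build_features(_analysis(), subset="all")
        v2 = build_features(_analysis(), subset="all")
        pd.testing.assert_series_equal(v1, v2, check_names=False)

    def test_subsets_are_disjoint_partitions_of_all(self):
        means, powers, inter = (
            ATTRIBUTE_SUBSETS["means"],
            ATTRIBUTE_SUBSETS["powers"],
            ATTRIBUTE_SUBSETS["interactions"],
        )
        assert len(set(means) & set(powers)) == 0
        assert len(set(powers) & set(inter)) == 0
        assert ATTRIBUTE_SUBSETS["all"] == means + powers + inter
        assert set(OPTIMAL12) <= set(ATTRIBUTE_SUBSETS["all"])


class TestDistance:
    def test_zero_for_identical(self):
        A = DistanceMetric.identity(["a", "b"])
        assert distance(np.array([1.0, 2.0]), np.array([1.0, 2.0]), A) == 0.0

    def test_euclidean_with_identity(self):
        A = DistanceMetric.identity(["a", "b", "c"])
        assert distance(np.array([3.0, 4.0, 0.0]), np.zeros(3), A) == pytest.approx(25.0)

    def test_diagonal_weighting(self):
        A = DistanceMetric(weights=np.array([2.0, 1.0]))
        assert distance(np.array([1.0, 1.0]), np.zeros(2), A) == pytest.approx(3.0)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 3, 5)
        A = DistanceMetric(weights=w)
        for _ in range(50):
            x, y, z = rng.standard_normal((3, 5))
            dxy = np.sqrt(distance(x, y, A))
            dyx = np.sqrt(distance(y, x, A))
            dxz = np.sqrt(distance(x, z, A))
            dzy = np.sqrt(distance(z, y, A))
            assert dxy == pytest.approx(dyx)
            assert dxy <= dxz + dzy + 1e-12

    def test_dimension_mismatch(self):
        A = DistanceMetric.identity(["a", "b"])
        with pytest.raises(DimensionMismatch):
            distance(np.zeros(3), np.zeros(3), A)


class TestLearnMetric:
    def test_informative_attribute_gets_top_weight(self):
        ft = make_feature_problem(informative=2, seed=1)
        metric = learn_metric(ft, seed=0)
        assert int(np.argmax(metric.weights)) == 2

    def test_uninformative_problem_keeps_identity(self):
        rng = np.random.default_rng(2)
        rows, states, subs = [], [], []
        for ci, c in enumerate(["awake", "sevoflurane", "propofol"]):
            for j in range(6):
                rows.append(pd.Series(rng.standard_normal(3), index=["a", "b", "c"]))
                states.append(c)
                subs.append(f"{c[:2]}{j}")
        ft = FeatureTable.from_rows(rows, states, subs)
        metric = learn_metric(ft, seed=0)
        base = learn_metric(ft, seed=0)
        np.testing.assert_allclose(metric.weights, base.weights)
        assert metric.weights.sum() == pytest.approx(3.0)

    def test_deterministic_given_seed(self):
        ft = make_feature_problem(seed=3)
        m1 = learn_metric(ft, seed=7)
        m2 = learn_metric(ft, seed=7)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_class_too_small(self):
        ft = make_feature_problem(n_per_class=3)
        with pytest.raises(ClassTooSmall):
            learn_metric(ft, seed=0)

    def test_never_below_identity_on_training_set(self):
        from cardiostate.classify import _identity_loocv_accuracy, _loso_accuracy, _pairwise_sq_diffs, _zscore_fit

        ft = make_feature_problem(noise=2.0, gap=3.0, seed=4)
        metric = learn_metric(ft, seed=0)
        ftc = ft.sorted_canonical()
        mu, sd = _zscore_fit(ftc.X)
        S = _pairwise_sq_diffs((ftc.X.to_numpy() - mu) / sd)
        acc_learned = _loso_accuracy(S, ftc.state, ftc.subject, metric.weights)
        acc_identity = _identity_loocv_accuracy(ft)
        assert acc_learned >= acc_identity


class TestNNClassify:
    def _train(self):
        rows = [
            pd.Series({"a": 0.0}), pd.Series({"a": 10.0}), pd.Series({"a": 20.0}),
        ]
        return FeatureTable.from_rows(rows, ["awake", "sevoflurane", "propofol"], ["s1", "s2", "s3"])

    def test_exact_match_returns_its_label(self):
        ft = self._train()
        A = DistanceMetric.identity(["a"])
        assert nn_classify(np.array([10.0]), ft, A) == "sevoflurane"

    def test_nearest_in_one_dimension(self):
        ft = self._train()
        A = DistanceMetric.identity(["a"])
        assert nn_classify(np.array([2.0]), ft, A) == "awake"

    def test_equidistant_tie_breaks_by_class_order(self):
        rows = [pd.Series({"a": -1.0}), pd.Series({"a": 1.0})]
        ft = FeatureTable.from_rows(rows, ["propofol", "sevoflurane"], ["p1", "s1"])
        A = DistanceMetric.identity(["a"])
        assert nn_classify(np.array([0.0]), ft, A) == "sevoflurane"

    def test_empty_training_set(self):
        ft = FeatureTable(X=pd.DataFrame(columns=["a"]), state=np.array([]), subject=np.array([]))
        with pytest.raises(EmptyTrainingSet):
            nn_classify(np.array([0.0]), ft, DistanceMetric.identity(["a"]))


class TestEvaluation:
    def test_separated_classes_loocv_perfect(self):
        ft = make_feature_problem(informative="all", gap=12.0, noise=0.3, seed=5)
        res = evaluate_loocv(ft, seed=0)
        assert res.accuracy == 1.0
        off_diag = res.confusion.counts.to_numpy() - np.diag(np.diag(res.confusion.counts.to_numpy()))
        assert off_diag.sum() == 0

    def test_confusion_rows_sum_to_100_percent(self):
        ft = make_feature_problem(gap=2.0, noise=1.0, seed=6)
        res = evaluate_holdout(ft, n_repeats=20, seed=1, learn=False)
        sums = res.confusion.row_percent.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_label_shuffle_gives_chance_level(self):
        # unstructured features; average over permutations (a single one has
        # ~0.1 sd on 24 subjects), 200 hold-out repeats in total
        ft = make_feature_problem(n_per_class=8, gap=0.0, noise=1.0, seed=7)
        rng = np.random.default_rng(0)
        accs = []
        for k in range(10):
            shuffled = FeatureTable(X=ft.X, state=rng.permutation(ft.state), subject=ft.subject)
            accs.append(evaluate_holdout(shuffled, n_repeats=20, seed=k, learn=False).accuracy)
        assert abs(np.mean(accs) - 1.0 / 3.0) < 0.05

    def test_loocv_not_worse_than_holdout_on_easy_cohort(self):
        ft = make_feature_problem(gap=6.0, noise=1.0, seed=8)
        loo = evaluate_loocv(ft, seed=0, learn=False)
        hold = evaluate_holdout(ft, n_repeats=50, seed=0, learn=False)
        assert loo.accuracy >= hold.accuracy - 1e-12

    def test_merged_two_state_mode(self):
        ft = make_feature_problem(gap=8.0, noise=0.5, seed=9)
        res = evaluate_loocv(ft, seed=0, learn=False, merge_anaes=True)
        assert res.classes == ["awake", "anaesthetised"]
        assert res.confusion.counts.shape == (2, 2)

    def test_deterministic_given_seed(self):
        ft = make_feature_problem(gap=2.0, noise=1.0, seed=10)
        r1 = evaluate_holdout(ft, n_repeats=10, seed=3, learn=False)
        r2 = evaluate_holdout(ft, n_repeats=10, seed=3, learn=False)
        pd.testing.assert_frame_equal(r1.confusion.counts, r2.confusion.counts)


class TestCascade:
    def test_informative_attribute_survives(self):
        ft = make_feature_problem(n_attrs=5, informative=3, seed=11)
        stages = attribute_cascade(ft, subsets={"toy": ft.attributes})
        merged = stages[-1]
        assert "attr_3" in merged.attributes

    def test_cascade_never_returns_empty_set(self):
        rng = np.random.default_rng(12)
        rows = [pd.Series(rng.standard_normal(3), index=["a", "b", "c"]) for _ in range(18)]
        states = (["awake"] * 6 + ["sevoflurane"] * 6 + ["propofol"] * 6)
        ft = FeatureTable.from_rows(rows, states, [f"s{j}" for j in range(18)])
        stages = attribute_cascade(ft, subsets={"noise": ["a", "b", "c"]})
        for st in stages:
            assert len(st.attributes) >= 1

    def test_merged_accuracy_not_below_best_subset(self):
        ft = make_feature_problem(n_attrs=6, informative=1, gap=6.0, noise=1.0, seed=13)
        subsets = {"first": ["attr_0", "attr_1", "attr_2"], "second": ["attr_3", "attr_4", "attr_5"]}
        stages = attribute_cascade(ft, subsets=subsets)
        merged = stages[-1].accuracy
        best_single = max(st.accuracy for st in stages[:-1])
        assert merged >= best_single - 1e-12
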