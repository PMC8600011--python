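import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nabind.dataset import augment_with_reverse
from nabind.errors import SchemaMismatchError
from nabind.model import (CVScheme, ModelConfig, classification_by_regression,
                          confusion_metrics, cross_validate,
                          evaluate_hotspot, evaluate_regression,
                          greedy_forward_selection, outlier_trimmed_metrics,
                          train)

from oracles import (formula_confusion, formula_kendall_tau_b,
                     formula_pearson, formula_rmse, formula_spearman)

FAST = ModelConfig(hyperparameters={"n_estimators": 40}, random_seed=0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = evaluate_regression([0, 1, 2, 3], [0, 1, 2, 3])
        assert (m["pearson"], m["spearman"], m["kendall"], m["rmse"]) == \
            (1.0, 1.0, 1.0, 0.0)

    def test_anticorrelated(self):
        m = evaluate_regression([0, 1, 2, 3], [0, -1, -2, -3])
        assert m["pearson"] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracles(self):
        yt = [0.0, 1.0, 2.0, 3.0]
        yp = [0.1, 0.9, 2.2, 2.8]
        m = evaluate_regression(yt, yp)
        assert m["pearson"] == pytest.approx(formula_pearson(yt, yp), abs=1e-9)
        assert m["spearman"] == pytest.approx(formula_spearman(yt, yp), abs=1e-9)
        assert m["kendall"] == pytest.approx(formula_kendall_tau_b(yt, yp),
                                             abs=1e-9)
        assert m["rmse"] == pytest.approx(formula_rmse(yt, yp), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestClassificationByRegression:
    def test_perfectly_separated(self):
        yt = [-2.0, -1.5, 1.2, 2.0]
        yp = [-1.9, -1.2, 1.0, 2.2]
        m = classification_by_regression(yt, yp)
        assert m["accuracy"] == 1.0 and m["mcc"] == 1.0 and m["auc"] == 1.0

    def test_neutral_records_excluded_from_n_used(self):
        yt = [-2.0, -0.2, 0.4, 1.5, -1.0]
        yp = [-1.0, 5.0, -5.0, 2.0, -0.5]
        m = classification_by_regression(yt, yp)
        assert m["n_used"] == 3

    def test_mcc_matches_closed_form_on_constructed_confusion(self):
        # TP=8 FP=2 TN=7 FN=3, built from signed ddG vectors outside the band
        yt = [1.0] * 8 + [-1.0] * 2 + [-1.0] * 7 + [1.0] * 3
        yp = [2.0] * 8 + [2.0] * 2 + [-2.0] * 7 + [-2.0] * 3
        m = classification_by_regression(yt, yp)
        oracle = formula_confusion(8, 2, 7, 3)
        assert m["mcc"] == pytest.approx(oracle["mcc"], abs=1e-12)
        assert m["f1"] == pytest.approx(oracle["f1"], abs=1e-12)
        assert m["accuracy"] == pytest.approx(oracle["acc"], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_by_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestOutlierTrimming:
    def test_fraction_zero_identical(self):
        yt = [0.0, 1.0, 2.0, 3.0]
        yp = [0.5, 0.8, 2.5, 2.0]
        full = evaluate_regression(yt, yp)
        trimmed = outlier_trimmed_metrics(yt, yp, 0.0)
        for k in full:
            assert trimmed[k] == full[k]

    def test_single_gross_outlier_removed(self):
        yt = list(range(10))
        yp = list(range(9)) + [100.0]
        m = outlier_trimmed_metrics(yt, yp, 0.10)
        assert m["pearson"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert m["n_used"] == 9

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_trimming_never_increases_rmse(self, seed):
        g = np.random.default_rng(seed)
        yt = g.normal(size=20)
        yp = yt + g.normal(scale=0.5, size=20)
        full = evaluate_regression(yt, yp)["rmse"]
        trimmed = outlier_trimmed_metrics(yt, yp, 0.10)["rmse"]
        assert trimmed <= full + 1e-12


class TestHotspotMetrics:
    def test_perfect_predictions(self):
        ddg = [-3.0, -2.5, -0.5, 0.2]
        m = evaluate_hotspot(ddg, ddg, cutoff=-2.0)
        assert all(m[k] == 1.0 for k in ("sen", "spe", "pre", "acc", "f1",
                                         "mcc"))

    def test_all_predicted_benign_has_zero_sensitivity(self):
        yt = [-3.0, -2.5, -0.5]
        yp = [0.0, 0.0, 0.0]
        assert evaluate_hotspot(yp, yt, cutoff=-2.0)["sen"] == 0.0

    def test_twenty_record_toy_matches_confusion_oracle(self, rng):
        yt = rng.uniform(-4, 2, size=20)
        yp = yt + rng.normal(scale=1.5, size=20)
        m = evaluate_hotspot(yp, yt, cutoff=-1.0)
        tp = int(np.sum((yt <= -1.0) & (yp <= -1.0)))
        fp = int(np.sum((yt > -1.0) & (yp <= -1.0)))
        tn = int(np.sum((yt > -1.0) & (yp > -1.0)))
        fn = int(np.sum((yt <= -1.0) & (yp > -1.0)))
        oracle = formula_confusion(tp, fp, tn, fn)
        for k in oracle:
            assert m[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_hotspot([], [], -2.0)


@given(st.tuples(st.integers(0, 60), st.integers(0, 60),
                 st.integers(0, 60), st.integers(0, 60)))
@settings(max_examples=200, deadline=None)
def test_confusion_metrics_agree_with_formula_oracle(table):
    tp, fp, tn, fn = table
    got = confusion_metrics(tp, fp, tn, fn)
    expected = formula_confusion(tp, fp, tn, fn)
    for k in expected:
        assert got[k] == pytest.approx(expected[k], abs=1e-9)


def _selection_frame(n=120, seed=0):
    g = np.random.default_rng(seed)
    signal = g.normal(size=n)
    frame = pd.DataFrame({f"noise{i}": g.normal(size=n) for i in range(10)})
    frame.insert(5, "signal", signal + g.normal(scale=0.01, size=n))
    target = signal
    groups = np.repeat([f"g{i}" for i in range(6)], n // 6)
    return frame, target, groups


class TestGreedySelection:
    def test_signal_feature_selected_first(self):
        frame, target, groups = _selection_frame()
        cfg = ModelConfig(hyperparameters={"n_estimators": 30}, random_seed=0,
                          max_selected_features=2)
        selected = greedy_forward_selection(frame, target, groups, cfg)
        assert selected[0] == "signal"

    def test_cap_of_one(self):
        frame, target, groups = _selection_frame()
        cfg = ModelConfig(hyperparameters={"n_estimators": 20}, random_seed=0,
                          max_selected_features=1)
        assert len(greedy_forward_selection(frame, target, groups, cfg)) == 1

    def test_deterministic_rerun(self):
        frame, target, groups = _selection_frame()
        cfg = ModelConfig(hyperparameters={"n_estimators": 25}, random_seed=7,
                          max_selected_features=3)
        a = greedy_forward_selection(frame, target, groups, cfg)
        b = greedy_forward_selection(frame, target, groups, cfg)
        assert a == b

    def test_degenerate_target_rejected(self):
        frame, _, groups = _selection_frame()
        with pytest.raises(ValueError):
            greedy_forward_selection(frame, np.zeros(len(frame)), groups, FAST)


def _linear_problem(n=240, sigma=0.2, seed=42, n_groups=8):
    g = np.random.default_rng(seed)
    x = pd.DataFrame(g.normal(size=(n, 6)),
                     columns=[f"f{i}" for i in range(6)])
    y = 2.0 * x["f0"] - 1.0 * x["f1"] + 0.5 * x["f2"] + \
        g.normal(scale=sigma, size=n)
    groups = np.array([f"g{i % n_groups}" for i in range(n)])
    return x, y.to_numpy(), groups


class TestCrossValidation:
    def test_loco_folds_partition_records(self):
        x, y, groups = _linear_problem(n=100, n_groups=5)
        scheme = CVScheme("leave-one-complex-out")
        folds = list(scheme.splitter().split(x, y, groups))
        assert len(folds) == 5
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(100))

    def test_group_integrity_across_schemes(self):
        x, y, groups = _linear_problem(n=120, n_groups=6)
        for scheme in (CVScheme("group-k-fold", 5),
                       CVScheme("leave-one-complex-out")):
            for train_idx, test_idx in scheme.splitter().split(x, y, groups):
                assert not (set(groups[train_idx]) & set(groups[test_idx]))

    def test_forward_reverse_partners_share_fold(self):
        from nabind.dataset import AffinityDataset
        from test_dataset import _record

        records = [_record(float(d), complex_id=f"c{i % 6}",
                           mutation=f"A R{i + 1}G")
                   for i, d in enumerate(np.linspace(-1.8, 1.8, 30))]
        ds = augment_with_reverse(AffinityDataset(records=records))
        groups = np.array(ds.groups())
        scheme = CVScheme("group-k-fold", 5)
        x = pd.DataFrame({"f": np.arange(len(ds), dtype=float)})
        y = np.array([r.ddg for r in ds])
        fold_of = {}
        for fold, (_, test_idx) in enumerate(
                scheme.splitter().split(x, y, groups)):
            for i in test_idx:
                fold_of[i] = fold
        by_id = {r.record_id: i for i, r in enumerate(ds.records)}
        for i, r in enumerate(ds.records):
            if r.forward_ref:
                assert fold_of[i] == fold_of[by_id[r.forward_ref]]

    def test_fewer_groups_than_folds_rejected(self):
        x, y, groups = _linear_problem(n=40, n_groups=3)
        with pytest.raises(ValueError):
            cross_validate(x, y, groups, CVScheme("group-k-fold", 5), FAST)

    def test_linear_recovery_and_noise_monotonicity(self):
        pearsons = []
        for sigma in (0.5, 0.1):
            x, y, groups = _linear_problem(sigma=sigma)
            report, preds = cross_validate(x, y, groups,
                                           CVScheme("group-k-fold", 5), FAST)
            assert len(preds) == len(y)
            pearsons.append(report.regression["pearson"])
        assert pearsons[0] >= 0.9
        assert pearsons[1] > pearsons[0]


class TestTrainPredict:
    def test_deterministic_with_fixed_seed(self):
        x, y, _ = _linear_problem(n=80)
        m1 = train(x, y, FAST)
        m2 = train(x, y, FAST)
        assert np.allclose(m1.predict(x), m2.predict(x))

    def test_predict_refuses_schema_mismatch(self):
        x, y, _ = _linear_problem(n=80)
        model = train(x, y, FAST)
        with pytest.raises(SchemaMismatchError):
            model.predict(x.rename(columns={"f0": "other"}))

    def test_bundle_roundtrip(self, tmp_path):
        x, y, _ = _linear_problem(n=80)
        model = train(x, y, FAST)
        path = tmp_path / "model.joblib"
        model.save(str(path))
        from nabind.model import TrainedModel

        loaded = TrainedModel.load(str(path))
        assert np.allclose(loaded.predict(x), model.predict(x))

    def test_feature_subset_training(self):
        x, y, _ = _linear_problem(n=80)
        model = train(x, y, FAST, feature_names=["f0", "f1"])
        assert model.feature_names == ["f0", "f1"]
        assert np.isfinite(model.predict(x)).all()
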