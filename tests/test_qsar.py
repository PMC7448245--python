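import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiscreen.chem_io import DescriptorMatrix, LabeledDataset, TargetConfig
from multiscreen.qsar import (
    ConfusionMatrix,
    ForestSpec,
    SplitSpec,
    confusion_metrics,
    cross_validate,
    model_esp,
    predict_activity_probability,
    roc_auc,
    stratified_split,
    train_forest,
    validate_on_test,
)
from multiscreen.synthdata import SimSpec, make_qsar_dataset


def _dataset(n_active, n_inactive, separation, seed, n_desc=10):
    return make_qsar_dataset(
        SimSpec(n_active=n_active, n_inactive=n_inactive, seed=seed,
                n_descriptors=n_desc, separation=separation)
    )


class TestStratifiedSplit:
    def test_exact_stratified_counts(self):
        ds = _dataset(60, 40, 3.0, seed=0)
        train, test = stratified_split(ds, SplitSpec(train_fraction=0.8, seed=0))
        assert train.n_active == 48 and train.n_inactive == 32
        assert test.n_active == 12 and test.n_inactive == 8

    def test_partition_disjoint_exhaustive_and_deterministic(self):
        ds = _dataset(30, 30, 3.0, seed=1)
        t1, s1 = stratified_split(ds, SplitSpec(seed=5))
        t2, s2 = stratified_split(ds, SplitSpec(seed=5))
        assert t1.X.compound_ids == t2.X.compound_ids
        union = set(t1.X.compound_ids) | set(s1.X.compound_ids)
        assert union == set(ds.X.compound_ids)
        assert not set(t1.X.compound_ids) & set(s1.X.compound_ids)

    def test_class_proportions_within_one_compound(self):
        ds = _dataset(57, 43, 2.0, seed=3)
        train, test = stratified_split(ds, SplitSpec(train_fraction=0.8, seed=2))
        for cls_total, tr in ((57, train.n_active), (43, train.n_inactive)):
            assert abs(tr - 0.8 * cls_total) <= 1

    def test_tiny_class_errors(self):
        ds = _dataset(1, 30, 2.0, seed=0)
        with pytest.raises(ValueError, match="2 members"):
            stratified_split(ds)


class TestTrainForest:
    def test_separable_data_high_training_accuracy(self):
        ds = _dataset(50, 50, 6.0, seed=2)
        model = train_forest(ds, ForestSpec(n_trees=100, seed=1))
        probs = predict_activity_probability(model, ds.X)
        acc = np.mean((probs >= 0.5).astype(int) == ds.y)
        assert acc >= 0.95

    def test_deterministic_for_fixed_seed(self):
        ds = _dataset(30, 30, 2.0, seed=4)
        p1 = predict_activity_probability(
            train_forest(ds, ForestSpec(n_trees=50, seed=9)), ds.X)
        p2 = predict_activity_probability(
            train_forest(ds, ForestSpec(n_trees=50, seed=9)), ds.X)
        np.testing.assert_array_equal(p1, p2)

    def test_probability_is_tree_vote_fraction(self):
        ds = _dataset(40, 40, 6.0, seed=5)
        model = train_forest(ds, ForestSpec(n_trees=50, seed=1))
        probs = predict_activity_probability(model, ds.X)
        assert np.all((probs >= 0) & (probs <= 1))
        # pure-signal data: training rows land on the correct side of 0.5
        assert np.all((probs >= 0.5) == (ds.y == 1))

    def test_descriptor_name_mismatch_errors(self):
        ds = _dataset(20, 20, 2.0, seed=6)
        model = train_forest(ds, ForestSpec(n_trees=10, seed=1))
        other = DescriptorMatrix(
            ds.X.compound_ids, [f"x{i}" for i in range(10)], ds.X.values)
        with pytest.raises(ValueError, match="descriptor names"):
            predict_activity_probability(model, other)


class TestConfusionMetrics:
    def test_perfect_prediction_mcc_is_one(self):
        assert confusion_metrics(ConfusionMatrix(10, 10, 0, 0)).mcc == 1.0

    def test_random_prediction_mcc_is_zero(self):
        assert confusion_metrics(ConfusionMatrix(25, 25, 25, 25)).mcc == 0.0

    def test_hand_computed_panel(self):
        rep = confusion_metrics(ConfusionMatrix(vp=50, vn=30, fp=20, fn=10))
        assert rep.mcc == pytest.approx(0.4485, abs=1e-4)
        assert rep.sensitivity == pytest.approx(50 / 60)
        assert rep.specificity == pytest.approx(30 / 50)
        assert rep.ppv == pytest.approx(50 / 70)
        assert rep.npv == pytest.approx(30 / 40)
        assert rep.accuracy == pytest.approx(80 / 110)

    def test_zero_denominator_reported_as_undefined(self):
        rep = confusion_metrics(ConfusionMatrix(vp=0, vn=10, fp=0, fn=0))
        assert rep.sensitivity is None and rep.ppv is None
        assert rep.specificity == 1.0

    @given(
        vp=st.integers(0, 50), vn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mcc_equals_pearson_of_binary_vectors(self, vp, vn, fp, fn):
        """The formula is the Pearson correlation of truth vs prediction."""
        if vp + vn + fp + fn == 0:
            return
        rep = confusion_metrics(ConfusionMatrix(vp, vn, fp, fn))
        truth = np.array([1] * vp + [0] * vn + [0] * fp + [1] * fn)
        pred = np.array([1] * vp + [0] * vn + [1] * fp + [0] * fn)
        if truth.std() == 0 or pred.std() == 0:
            assert rep.mcc is None
        else:
            assert rep.mcc == pytest.approx(np.corrcoef(truth, pred)[0, 1])

    @given(
        vp=st.integers(1, 50), vn=st.integers(1, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_accuracy_is_prevalence_weighted_mean(self, vp, vn, fp, fn):
        rep = confusion_metrics(ConfusionMatrix(vp, vn, fp, fn))
        p, n = vp + fn, vn + fp
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * p + rep.specificity * n) / (p + n))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pair_count(self):
        # actives 0.9, 0.8; inactives 0.7, 0.85 -> 3 of 4 concordant pairs
        assert roc_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]) == 0.75

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert 0.45 < roc_auc(scores, labels) < 0.55

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.5, 0.6], [1, 1])


class TestCrossValidate:
    def test_pure_noise_mcc_near_zero(self):
        ds = _dataset(100, 100, 0.0, seed=11)
        rep = cross_validate(ds, ForestSpec(n_trees=100, seed=1), k=10)
        assert abs(rep.mcc) <= 0.2

    def test_separated_classes_recovered(self):
        ds = _dataset(100, 100, 6.0, seed=12)
        rep = cross_validate(ds, ForestSpec(n_trees=100, seed=1), k=10)
        assert rep.mcc >= 0.9
        assert rep.validation_mode == "cross"

    def test_k_below_two_errors(self):
        ds = _dataset(20, 20, 2.0, seed=13)
        with pytest.raises(ValueError, match="k >= 2"):
            cross_validate(ds, k=1)


class TestModelEsp:
    def test_reference_specificity_mean(self):
        t = confusion_metrics(ConfusionMatrix(81, 81, 19, 19))
        c = confusion_metrics(ConfusionMatrix(82, 82, 18, 18))
        assert model_esp(t, c) == pytest.approx((0.81 + 0.82) / 2)

    def test_equal_specificities_fixed_point(self):
        rep = confusion_metrics(ConfusionMatrix(10, 8, 2, 3))
        assert model_esp(rep, rep) == rep.specificity

    def test_missing_specificity_errors(self):
        good = confusion_metrics(ConfusionMatrix(10, 8, 2, 3))
        bad = confusion_metrics(ConfusionMatrix(vp=5, vn=0, fp=0, fn=5))
        with pytest.raises(ValueError, match="specificity"):
            model_esp(good, bad)


def test_test_and_cross_reports_feed_esp_end_to_end():
    ds = _dataset(60, 60, 6.0, seed=21)
    train, test = stratified_split(ds, SplitSpec(seed=1))
    model = train_forest(train, ForestSpec(n_trees=100, seed=1))
    test_rep = validate_on_test(model, test)
    cross_rep = cross_validate(ds, ForestSpec(n_trees=100, seed=1), k=5)
    esp = model_esp(test_rep, cross_rep)
    assert 0 <= esp <= 1
    assert test_rep.roc_auc >= 0.9
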