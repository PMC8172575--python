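import random

import numpy as np
import pytest

import senseinv as si


def _pair(i, values, label):
    return si.LabeledPair(
        pair_id=(f"R{2 * i + 1:06d}", f"R{2 * i + 2:06d}"),
        features=si.PairFeatures(*values),
        label=label,
    )


def separable_data(n_per_class=40, seed=0):
    """Positives: all features >= 0.9; negatives: all <= 0.3."""
    rng = random.Random(seed)
    data = []
    for i in range(n_per_class):
        data.append(_pair(i, tuple(rng.uniform(0.9, 1.0) for _ in range(5)), 1))
        data.append(
            _pair(n_per_class + i, tuple(rng.uniform(0.0, 0.3) for _ in range(5)), 0)
        )
    return data


@pytest.fixture(scope="module")
def separable():
    return separable_data()


class TestTrainClassifier:
    @pytest.mark.parametrize("backend", ["lightgbm", "logistic"])
    def test_separable_data_classified_at_half(self, separable, backend):
        model = si.train_classifier(separable, seed=0, backend=backend)
        X = np.array([p.features.as_tuple() for p in separable])
        y = np.array([p.label for p in separable])
        assert ((model.predict_proba(X) >= 0.5).astype(int) == y).all()

    def test_empty_data_errors(self):
        with pytest.raises(ValueError):
            si.train_classifier([])

    def test_single_class_errors(self):
        data = [_pair(i, (0.9,) * 5, 1) for i in range(10)]
        with pytest.raises(ValueError):
            si.train_classifier(data)

    def test_deterministic_under_seed(self, separable):
        X = np.array([p.features.as_tuple() for p in separable])
        probs_a = si.train_classifier(separable, seed=3).predict_proba(X)
        probs_b = si.train_classifier(separable, seed=3).predict_proba(X)
        assert np.array_equal(probs_a, probs_b)

    def test_save_load_round_trip(self, separable, tmp_path):
        model = si.train_classifier(separable, seed=0)
        X = np.array([p.features.as_tuple() for p in separable])
        path = model.save(tmp_path / "model.bin")
        loaded = si.SynonymClassifier.load(path)
        assert np.array_equal(loaded.predict_proba(X), model.predict_proba(X))
        assert loaded.feature_names == si.FEATURE_NAMES


class TestCrossvalidate:
    def test_separable_data_perfect_f1(self, separable):
        report = si.crossvalidate(separable, k=5, seed=0)
        assert report.mean_f1 == 1.0
        assert len(report.per_fold) == 5

    def test_shuffled_labels_f1_near_prevalence(self):
        # permutation null: features carry no signal, F1 ~ prevalence (0.5)
        rng = random.Random(9)
        data = [
            _pair(i, tuple(rng.random() for _ in range(5)), i % 2) for i in range(200)
        ]
        report = si.crossvalidate(data, k=5, seed=0)
        assert abs(report.mean_f1 - 0.5) < 0.2

    def test_k_below_two_errors(self, separable):
        with pytest.raises(ValueError):
            si.crossvalidate(separable, k=1)

    def test_class_smaller_than_k_errors(self):
        data = separable_data(n_per_class=3)
        with pytest.raises(ValueError, match="class"):
            si.crossvalidate(data, k=5)

    def test_invariant_to_row_order(self, separable):
        baseline = si.crossvalidate(separable, k=5, seed=1)
        shuffled = list(separable)
        random.Random(4).shuffle(shuffled)
        assert si.crossvalidate(shuffled, k=5, seed=1) == baseline

    def test_f1_consistent_with_precision_recall(self, separable):
        report = si.crossvalidate(separable, k=5, seed=0)
        for fold in report.per_fold:
            if fold.precision + fold.recall:
                expected = 2 * fold.precision * fold.recall / (fold.precision + fold.recall)
            else:
                expected = 0.0
            assert fold.f1 == pytest.approx(expected)


def _sweep_oracle(probs, labels, target):
    """Exhaustive smallest-threshold search over observed probabilities."""
    best = None
    for t in sorted(set(probs)):
        pred = [p >= t for p in probs]
        if not any(pred):
            continue
        hits = sum(l for p, l in zip(pred, labels) if p)
        if hits / sum(pred) >= target:
            best = t
            break
    return best


class TestSelectThreshold:
    def test_two_point_case(self, separable):
        model = si.train_classifier(separable, seed=0)
        validation = separable_data(n_per_class=10, seed=5)
        t = si.select_threshold(model, validation, target_precision=0.99)
        X = np.array([p.features.as_tuple() for p in validation])
        y = np.array([p.label for p in validation])
        assert (((si.train_classifier(separable, seed=0).predict_proba(X) >= t)
                 .astype(int)) == y).all()

    def test_matches_exhaustive_sweep(self, separable):
        model = si.train_classifier(separable, seed=0)
        validation = separable_data(n_per_class=15, seed=8)
        X = np.array([p.features.as_tuple() for p in validation])
        probs = model.predict_proba(X)
        labels = [p.label for p in validation]
        # align prob/label order with the canonical order used internally
        order = sorted(range(len(validation)),
                       key=lambda i: (validation[i].label,
                                      validation[i].features.as_tuple(),
                                      validation[i].pair_id))
        expected = _sweep_oracle([probs[i] for i in order], [labels[i] for i in order], 0.99)
        assert si.select_threshold(model, validation, 0.99) == pytest.approx(expected)

    def test_target_zero_returns_minimum_probability(self, separable):
        model = si.train_classifier(separable, seed=0)
        X = np.array([p.features.as_tuple() for p in separable])
        t = si.select_threshold(model, separable, target_precision=0.0)
        assert t == pytest.approx(model.predict_proba(X).min())

    def test_unattainable_target_warns(self):
        # constant features: no threshold can separate the classes
        data = [_pair(i, (0.5,) * 5, i % 2) for i in range(20)]
        model = si.train_classifier(data, seed=0, backend="logistic")
        with pytest.warns(si.ThresholdWarning):
            si.select_threshold(model, data, target_precision=0.999)

    def test_single_class_validation_errors(self, separable):
        model = si.train_classifier(separable, seed=0)
        positives = [p for p in separable if p.label == 1]
        with pytest.raises(ValueError):
            si.select_threshold(model, positives)
        with pytest.raises(ValueError):
            si.select_threshold(model, [])


class TestPredictPairs:
    def _featurized(self, separable):
        return [
            (si.CandidatePair(*p.pair_id, True, 0.9), p.features) for p in separable
        ]

    def test_threshold_zero_all_positive(self, separable):
        model = si.train_classifier(separable, seed=0)
        predictions = si.predict_pairs(model, self._featurized(separable), 0.0)
        assert all(p.is_synonym for p in predictions)

    def test_threshold_above_one_rejected(self, separable):
        model = si.train_classifier(separable, seed=0)
        with pytest.raises(ValueError):
            si.predict_pairs(model, self._featurized(separable), 1.1)

    def test_output_order_matches_input(self, separable):
        model = si.train_classifier(separable, seed=0)
        featurized = self._featurized(separable)
        predictions = si.predict_pairs(model, featurized, 0.5)
        assert [p.pair for p in predictions] == [pair for pair, _ in featurized]

    def test_raising_threshold_monotone(self, separable):
        model = si.train_classifier(separable, seed=0)
        featurized = self._featurized(separable)
        counts = [
            sum(p.is_synonym for p in si.predict_pairs(model, featurized, t))
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_separable_fixture_matches_truth_at_selected_threshold(self, separable):
        model = si.train_classifier(separable, seed=0)
        t = si.select_threshold(model, separable, target_precision=0.99)
        predictions = si.predict_pairs(model, self._featurized(separable), t)
        assert [int(p.is_synonym) for p in predictions] == [p.label for p in separable]
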