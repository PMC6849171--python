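"""Ordinal decomposition wrapper, training contracts and
cross-validation mechanics."""

import warnings

import numpy as np
import pytest

from kneetext.classify import (
    ClassifierSpec,
    CrossValidationPlan,
    OrdinalClassifier,
    compose_ordinal_probabilities,
    cross_validate,
    ordinal_wrap,
    train,
)
from kneetext.features import FeatureVector


def make_vectors(X, y=None, names=None, fingerprint="fp"):
    names = names or [f"f{i}" for i in range(len(X[0]))]
    return [
        FeatureVector(
            response_id=f"r{i}",
            question_id="Q6",
            values=[float(v) for v in row],
            column_names=names,
            gold=None if y is None else int(y[i]),
            schema_fingerprint=fingerprint,
        )
        for i, row in enumerate(X)
    ]


def monotone_data(rng, n=90, noise=0.0):
    """Feature 0 equals the class, plus distractor noise columns."""
    y = rng.integers(1, 4, size=n)
    X = np.column_stack([
        y + noise * rng.normal(size=n),
        rng.normal(size=n),
        rng.uniform(size=n),
    ])
    return X, y


class TestDecomposition:
    def test_threshold_arithmetic(self):
        probs = compose_ordinal_probabilities(np.array([[0.9, 0.2]]))
        assert probs[0] == pytest.approx([0.1, 0.7, 0.2])

    def test_inconsistent_thresholds_clip_and_renormalize(self):
        probs = compose_ordinal_probabilities(np.array([[0.2, 0.9]]))[0]
        assert probs[1] == 0.0
        assert probs.sum() == pytest.approx(1.0)
        assert np.argmax(probs) == 2  # class 3 after clipping

    def test_probabilities_sum_to_one_everywhere(self):
        rng = np.random.default_rng(0)
        exceed = rng.uniform(size=(500, 2))
        probs = compose_ordinal_probabilities(exceed)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_binary_case_equals_base_classifier(self):
        rng = np.random.default_rng(1)
        n = 80
        y = rng.integers(1, 3, size=n)
        X = np.column_stack([y + 0.2 * rng.normal(size=n), rng.normal(size=n)])
        base = ClassifierSpec("naive-bayes")
        vecs = make_vectors(X, y)
        plain = train(vecs, base).predict(vecs)
        wrapped = train(vecs, ordinal_wrap(base, 2)).predict(vecs)
        assert (plain == wrapped).all()

    def test_wrap_requires_two_classes(self):
        with pytest.raises(ValueError):
            ordinal_wrap(ClassifierSpec("naive-bayes"), 1)
        with pytest.raises(ValueError):
            OrdinalClassifier(ClassifierSpec("naive-bayes"), classes=[1])


class TestTrain:
    def test_separable_data_perfect_resubstitution(self):
        rng = np.random.default_rng(2)
        X, y = monotone_data(rng, noise=0.0)
        vecs = make_vectors(X, y)
        model = train(vecs, ClassifierSpec("naive-bayes", ordinal=True))
        assert (model.predict(vecs) == y).mean() == 1.0

    def test_contradictory_duplicates_still_train(self):
        vecs = make_vectors([[1.0, 0.0], [1.0, 0.0], [2.0, 0.0]], [1, 2, 2])
        model = train(vecs, ClassifierSpec("naive-bayes"))
        assert model.predict(vecs[:1])[0] in (1, 2)

    def test_single_class_is_hard_error(self):
        vecs = make_vectors([[1.0], [2.0]], [1, 1])
        with pytest.raises(ValueError, match="single class"):
            train(vecs, ClassifierSpec("naive-bayes"))

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        X, y = monotone_data(rng, n=30)
        model = train(make_vectors(X, y, fingerprint="A"), ClassifierSpec("naive-bayes"))
        with pytest.raises(ValueError, match="fingerprint"):
            model.predict(make_vectors(X[:5], fingerprint="B"))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="roster"):
            ClassifierSpec("svm")

    def test_fixed_seed_serializes_identically(self, tmp_path):
        rng = np.random.default_rng(4)
        X, y = monotone_data(rng, n=60, noise=0.3)
        spec = ClassifierSpec("random-forest", seed=7)
        for name in ("a", "b"):
            train(make_vectors(X, y), spec).save(tmp_path / name)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()


class TestCrossValidation:
    def test_every_instance_tested_exactly_once(self):
        rng = np.random.default_rng(5)
        X, y = monotone_data(rng, n=30, noise=0.2)
        cm = cross_validate(
            make_vectors(X, y), ClassifierSpec("naive-bayes"), CrossValidationPlan(k=10, seed=0)
        )
        assert cm.total == 30

    def test_perfect_rule_gives_diagonal_matrix(self):
        rng = np.random.default_rng(6)
        X, y = monotone_data(rng, n=120, noise=0.0)
        cm = cross_validate(
            make_vectors(X, y),
            ClassifierSpec("naive-bayes", ordinal=True),
            CrossValidationPlan(k=10, seed=0),
        )
        assert cm.counts.sum() == np.trace(cm.counts)

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(7)
        X, y = monotone_data(rng, n=50, noise=0.5)
        plan = CrossValidationPlan(k=5, seed=11)
        a = cross_validate(make_vectors(X, y), ClassifierSpec("decision-tree-pruned"), plan)
        b = cross_validate(make_vectors(X, y), ClassifierSpec("decision-tree-pruned"), plan)
        assert (a.counts == b.counts).all()

    def test_too_few_instances_is_hard_error(self):
        vecs = make_vectors([[1.0], [2.0], [3.0]], [1, 2, 3])
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(vecs, ClassifierSpec("naive-bayes"), CrossValidationPlan(k=10))

    def test_small_class_falls_back_to_plain_folds_with_warning(self):
        rng = np.random.default_rng(8)
        X, y = monotone_data(rng, n=40, noise=0.2)
        y[:2] = 1
        y[2:] = rng.integers(2, 4, size=38)
        X[:, 0] = y
        with pytest.warns(UserWarning, match="fewer members"):
            cross_validate(
                make_vectors(X, y), ClassifierSpec("naive-bayes"), CrossValidationPlan(k=10)
            )

    def test_ordinal_wrapper_not_worse_than_base(self):
        """Monotone signal: wrapped accuracy within 2 points of the base
        classifier, averaged over seeded replicates."""
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, y = monotone_data(rng, n=60, noise=0.6)
            vecs = make_vectors(X, y)
            plan = CrossValidationPlan(k=5, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base_cm = cross_validate(vecs, ClassifierSpec("naive-bayes"), plan)
                wrap_cm = cross_validate(
                    vecs, ClassifierSpec("naive-bayes", ordinal=True), plan
                )
            acc = lambda cm: np.trace(cm.counts) / cm.total
            deltas.append(acc(wrap_cm) - acc(base_cm))
        assert float(np.mean(deltas)) >= -0.02
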