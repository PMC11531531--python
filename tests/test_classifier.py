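"""Fuzzy deep classifier: activation primitives, training, prediction."""

import numpy as np
import pytest

import fuzzyhisto as fh
from fuzzyhisto.classifier import defuzzify, fuzzify, relu, softmax


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (5.0, 5.0),
                                            (0.0, 0.0)])
    def test_relu_scalar_branches(self, x, expected):
        assert relu(x) == expected

    def test_relu_elementwise(self):
        assert np.array_equal(relu(np.array([-1.0, 2.0, 0.0])),
                              np.array([0.0, 2.0, 0.0]))

    @pytest.mark.parametrize("z,expected", [
        ([0.0, 0.0], [0.5, 0.5]),
        ([1.0, 1.0, 1.0], [1 / 3] * 3),
    ])
    def test_softmax_symmetry(self, z, expected):
        assert np.allclose(softmax(z), expected)

    def test_softmax_shift_invariant_and_stable(self):
        z = np.array([1.0, 2.0, 3.0])
        assert np.allclose(softmax(z), softmax(z + 100.0))
        big = softmax(np.array([1000.0, 0.0]))
        assert np.isfinite(big).all()
        assert big[0] == pytest.approx(1.0)
        assert big.sum() == pytest.approx(1.0)


@pytest.fixture
def tiny_rule_base():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 2.0]])
    y = np.array([0, 0, 1, 1])
    parts = fh.build_partitions(X, n_levels=3)
    return fh.wang_mendel(X, y, parts), X, y


class TestFuzzify:
    def test_sample_at_every_apex_fires_fully(self, tiny_rule_base):
        base, X, _ = tiny_rule_base
        alpha = fuzzify(X, base)
        # each training sample sits at the apexes of its own rule
        assert alpha.max(axis=1) == pytest.approx(np.ones(len(X)))

    def test_zero_factor_annihilates(self, tiny_rule_base):
        base, _, _ = tiny_rule_base
        # far outside every support in variable 0
        alpha = fuzzify(np.array([[100.0, 1.0]]), base)
        assert np.allclose(alpha, 0.0)

    def test_matches_per_factor_bruteforce(self, tiny_rule_base):
        base, _, _ = tiny_rule_base
        rng = np.random.default_rng(0)
        Xq = rng.uniform(0, 2, size=(10, 2))
        alpha = fuzzify(Xq, base)
        for s in range(10):
            for i, rule in enumerate(base.rules):
                expected = 1.0
                for j, part in enumerate(base.partitions):
                    expected *= fh.eval_mf(part.mfs[rule.antecedent[j]],
                                           Xq[s, j])
                assert alpha[s, i] == pytest.approx(expected, abs=1e-12)

    def test_bounded_unit_interval(self, tiny_rule_base):
        base, _, _ = tiny_rule_base
        alpha = fuzzify(np.random.default_rng(1).uniform(-5, 5, (50, 2)), base)
        assert (alpha >= 0).all() and (alpha <= 1).all()


class TestDefuzzify:
    def test_one_hot_selects_weight_row(self):
        w = np.arange(12.0).reshape(6, 2)
        alpha = np.zeros(6)
        alpha[3] = 1.0
        assert np.array_equal(defuzzify(alpha, w), w[3])

    def test_zero_activation_zero_scores(self):
        assert np.allclose(defuzzify(np.zeros(4), np.ones((4, 2))), 0.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(2)
        alpha, w = rng.uniform(size=(3, 5)), rng.normal(size=(5, 2))
        beta = defuzzify(alpha, w)
        for s in range(3):
            for k in range(2):
                assert beta[s, k] == pytest.approx(
                    sum(alpha[s, i] * w[i, k] for i in range(5)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            defuzzify(np.ones(3), np.ones((4, 2)))


class TestTraining:
    def test_separable_data_recovered(self, separable_table):
        accs = []
        for seed in range(5):
            m = fh.FuzzyDeepClassifier(hidden_dim=32, epochs=5,
                                       random_state=seed)
            m.fit(separable_table.matrix, separable_table.labels,
                  separable_table.feature_ids)
            accs.append(m.history_["val_accuracy"][-1])
        assert min(accs) >= 0.95

    def test_shuffled_labels_near_chance(self, separable_table):
        accs = []
        for seed in range(3):
            yp = np.random.default_rng(seed).permutation(
                separable_table.labels)
            m = fh.FuzzyDeepClassifier(hidden_dim=32, epochs=5,
                                       random_state=seed)
            m.fit(separable_table.matrix, yp, separable_table.feature_ids)
            accs.append(m.history_["val_accuracy"][-1])
        assert all(0.35 <= a <= 0.65 for a in accs)

    def test_deterministic_weights_under_fixed_seed(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=30, n_features=10, n_informative=3, seed=2))
        runs = [fh.FuzzyDeepClassifier(hidden_dim=16, epochs=3,
                                       random_state=7).fit(
                    tab.matrix, tab.labels, tab.feature_ids)
                for _ in range(2)]
        for attr in ("W1_", "b1_", "W3h_", "W3r_", "b3_"):
            assert np.array_equal(getattr(runs[0], attr),
                                  getattr(runs[1], attr))

    def test_history_has_loss_and_accuracy_curves(self, separable_table):
        m = fh.FuzzyDeepClassifier(hidden_dim=16, epochs=4, random_state=0)
        m.fit(separable_table.matrix, separable_table.labels)
        for key in ("train_loss", "val_loss", "train_accuracy",
                    "val_accuracy"):
            assert len(m.history_[key]) == 4
        assert m.history_["train_loss"][-1] < m.history_["train_loss"][0]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError, match="class"):
            fh.FuzzyDeepClassifier(epochs=1).fit(X, np.zeros(20, int))

    def test_overcapacity_model_memorizes_training_set(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=20, n_features=8, n_informative=4,
            class_separation=3.0, seed=5))
        m = fh.FuzzyDeepClassifier(hidden_dim=128, epochs=150,
                                   validation_fraction=0.2, random_state=1)
        m.fit(tab.matrix, tab.labels, tab.feature_ids)
        tr = m.train_indices_
        assert (m.predict(tab.matrix[tr]) == tab.labels[tr]).mean() >= 0.97


class TestPredict:
    def test_probability_rows_sum_to_one(self, separable_table):
        m = fh.FuzzyDeepClassifier(hidden_dim=16, epochs=2, random_state=0)
        m.fit(separable_table.matrix, separable_table.labels)
        proba = m.predict_proba(separable_table.matrix)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba > 0).all()

    def test_predict_consistent_with_proba(self, separable_table):
        m = fh.FuzzyDeepClassifier(hidden_dim=16, epochs=2, random_state=0)
        m.fit(separable_table.matrix, separable_table.labels)
        proba = m.predict_proba(separable_table.matrix)
        assert np.array_equal(m.predict(separable_table.matrix),
                              m.classes_[proba.argmax(axis=1)])

    def test_schema_mismatch_rejected(self, separable_table):
        m = fh.FuzzyDeepClassifier(hidden_dim=8, epochs=1, random_state=0)
        m.fit(separable_table.matrix, separable_table.labels)
        with pytest.raises(ValueError, match="feature columns"):
            m.predict(separable_table.matrix[:, :5])

    def test_sklearn_get_set_params_roundtrip(self):
        m = fh.FuzzyDeepClassifier(hidden_dim=17)
        assert m.get_params()["hidden_dim"] == 17
        m.set_params(epochs=3)
        assert m.epochs == 3


def test_train_function_wrapper(separable_table):
    cfg = fh.TrainConfig(epochs=3, seed=1)
    model, history = fh.train(separable_table, cfg=cfg, hidden_dim=16)
    assert len(history["val_accuracy"]) == 3
    proba, labels = fh.predict(model, separable_table)
    assert proba.shape == (separable_table.n_samples, 2)
    assert set(labels) <= {0, 1}
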