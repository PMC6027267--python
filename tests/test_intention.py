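"""Intention classifiers, limb-motion detection and gating."""

import itertools

import numpy as np
import pytest

from eegintent.core_io import KinematicsTrace
from eegintent.intention import (
    GatingRule,
    KNNSpec,
    MLPSpec,
    TrainedIntentionModel,
    _knn_predict_raw,
    chronological_split,
    discretize,
    gate,
    limb_motion_flag,
    predict_continuous,
    predict_knn,
    train_knn,
    train_mlp,
)


@pytest.fixture(scope="module")
def separable_fixture():
    """Three well-separated Gaussian clusters with codes -1/0/+1."""
    rng = np.random.default_rng(0)
    n = 200
    X = np.vstack(
        [
            rng.normal([0.0, 2.0], 0.3, (n, 2)),
            rng.normal([-2.0, -1.0], 0.3, (n, 2)),
            rng.normal([2.0, -1.0], 0.3, (n, 2)),
        ]
    )
    y = np.r_[np.ones(n, int), np.zeros(n, int), -np.ones(n, int)]
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestMLP:
    def test_learns_separable_classes(self, separable_fixture):
        X, y = separable_fixture
        spec = MLPSpec(n_inputs=2, epochs=500, seed=1)
        model = train_mlp(X, y, spec)
        pred = discretize(predict_continuous(model, X))
        assert np.mean(pred == y) >= 0.95

    def test_deterministic_under_fixed_seed(self, separable_fixture):
        X, y = separable_fixture
        spec = MLPSpec(n_inputs=2, epochs=100, seed=3)
        m1 = train_mlp(X, y, spec)
        m2 = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=100, seed=3))
        np.testing.assert_array_equal(m1.net.w1, m2.net.w1)
        np.testing.assert_array_equal(m1.net.w2, m2.net.w2)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate labels"):
            train_mlp(np.zeros((50, 2)), np.zeros(50, int))

    def test_outputs_bounded(self, separable_fixture):
        X, y = separable_fixture
        model = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=200, seed=0))
        out = predict_continuous(model, np.random.default_rng(0).normal(0, 50, (100, 2)))
        assert (out >= -1).all() and (out <= 1).all()

    def test_training_targets_recovered(self, separable_fixture):
        X, y = separable_fixture
        model = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=500, seed=1))
        out = predict_continuous(model, X)
        assert np.mean(np.abs(out - y)) <= 0.2

    def test_pure_noise_features_carry_no_class_signal(self):
        """Class-conditional output means on noise features differ by less
        than twice the standard error."""
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (900, 4))
        y = rng.choice([-1, 0, 1], 900)
        tr, te = chronological_split(900)
        model = train_mlp(X[tr], y[tr], MLPSpec(n_inputs=4, epochs=200, seed=0))
        out = predict_continuous(model, X[te])
        grp = [out[y[te] == c] for c in (-1, 1)]
        se = np.sqrt(sum(g.var(ddof=1) / len(g) for g in grp))
        assert abs(grp[0].mean() - grp[1].mean()) < 2 * se

    def test_loss_decreases_monotonically_after_momentum_transient(
        self, separable_fixture
    ):
        """Past the initial momentum ramp the training MSE never rises by
        more than 1% per epoch, and ends well below where it started."""
        X, y = separable_fixture
        model = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=500, seed=2))
        lh = np.array(model.net.loss_history)
        rel_inc = (lh[101:] - lh[100:-1]) / lh[100:-1]
        assert rel_inc.max() <= 0.01
        assert lh[-1] < 0.5 * lh[0]

    def test_dimension_mismatch_rejected(self, separable_fixture):
        X, y = separable_fixture
        model = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=50, seed=0))
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict_continuous(model, np.zeros((5, 3)))

    def test_save_load_round_trip(self, separable_fixture, tmp_path):
        X, y = separable_fixture
        model = train_mlp(X, y, MLPSpec(n_inputs=2, epochs=100, seed=0))
        model.save(tmp_path / "m.json")
        back = TrainedIntentionModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(
            predict_continuous(back, X[:20]), predict_continuous(model, X[:20])
        )


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0), (0.9, 1), (-0.9, -1), (0.5, 0), (-0.5, 0), (0.51, 1)],
    )
    def test_threshold_rule(self, value, expected):
        assert discretize(np.array([value]))[0] == expected


class TestKNN:
    def test_cv_selected_model_on_clusters(self, separable_fixture):
        X, y = separable_fixture
        tr, te = chronological_split(len(y))
        model = train_knn(X[tr], y[tr])
        pred = predict_knn(model, X[te])
        assert np.mean(pred == y[te]) >= 0.95

    def test_one_nn_recalls_training_points(self, separable_fixture):
        X, y = separable_fixture
        model = train_knn(X, y, k_grid=[1], metrics=["euclidean"],
                          votes=["majority"])
        assert np.mean(predict_knn(model, X) == y) == 1.0

    def test_matches_brute_force_oracle(self, separable_fixture):
        """Library-backed neighbor search equals an explicit distance scan."""
        X, y = separable_fixture
        rng = np.random.default_rng(7)
        model = train_knn(X[:300], y[:300])
        queries = rng.normal(0, 2, (50, 2))
        got = predict_knn(model, queries)
        qz = (queries - model.scaler_mean) / model.scaler_std
        k, metric, vote = model.spec.k, model.spec.metric, model.spec.vote
        expected = []
        for q in qz:
            if metric == "euclidean":
                d = np.sqrt(((model.train_X - q) ** 2).sum(1))
            elif metric == "cityblock":
                d = np.abs(model.train_X - q).sum(1)
            else:
                norm = np.linalg.norm(model.train_X, axis=1) * np.linalg.norm(q)
                d = 1 - (model.train_X @ q) / np.where(norm > 0, norm, 1.0)
            order = np.argsort(d, kind="stable")[:k]
            w = np.ones(k) if vote == "majority" else 1 / (1 + d[order])
            scores = {c: w[model.train_y[order] == c].sum() for c in (-1, 0, 1)}
            top = max(scores.values())
            tied = [c for c, s in scores.items() if s >= top - 1e-12]
            expected.append(0 if 0 in tied else min(tied))
        np.testing.assert_array_equal(got, expected)

    def test_majority_and_weighted_agree_on_clear_majorities(self):
        """Whenever one class holds more than k/2 neighbors the two vote
        rules coincide (enumerated over small neighbor sets)."""
        for k in (1, 3, 5):
            for combo in itertools.product((-1, 0, 1), repeat=k):
                labels = np.array([combo])
                dists = np.linspace(0.1, 1.0, k)[None, :]
                counts = {c: combo.count(c) for c in (-1, 0, 1)}
                if max(counts.values()) <= k / 2:
                    continue
                from eegintent.intention import _vote

                maj = _vote(labels, dists, "majority")[0]
                sim = _vote(labels, dists, "similarity_weighted")[0]
                assert maj == sim == max(counts, key=counts.get)

    def test_tie_breaks_toward_rest(self):
        train_X = np.array([[0.0, 1.0], [0.0, -1.0]])
        train_y = np.array([1, 0])
        pred = _knn_predict_raw(
            train_X, train_y, np.array([[0.0, 0.0]]), KNNSpec(k=2)
        )
        assert pred[0] == 0

    def test_single_training_point_maps_everything(self):
        model = train_knn(
            np.array([[0.0], [0.0]]), np.array([1, 1]),
            k_grid=[1], metrics=["euclidean"], votes=["majority"], n_folds=2,
        )
        assert (predict_knn(model, np.array([[5.0], [-5.0]])) == 1).all()


class TestLimbMotion:
    def _kin(self, shoulder, fs=500.0):
        n = len(shoulder)
        return KinematicsTrace(fs, shoulder, np.full(n, 170.0), np.zeros((n, 2)))

    def test_constant_angle_never_flags(self):
        assert not limb_motion_flag(self._kin(np.full(3000, 20.0))).any()

    def test_ramp_flags_during_motion(self):
        """0 to 90 degrees over 2 s (45 deg/s) is well above threshold."""
        fs = 500.0
        shoulder = np.r_[
            np.zeros(1000), np.linspace(0, 90, 1000), np.full(1000, 90.0)
        ]
        flag = limb_motion_flag(self._kin(shoulder, fs))
        assert flag[1200:1800].all()
        assert not flag[:800].any()
        assert not flag[2400:].any()

    def test_single_sample_spike_suppressed(self):
        shoulder = np.full(3000, 10.0)
        shoulder[1500] = 11.0
        assert not limb_motion_flag(self._kin(shoulder)).any()


class TestGating:
    def test_exhaustive_truth_table(self):
        """All six (prediction, limb-moving) combinations."""
        pred = np.array([0, -1, 1, 0, -1, 1])
        moving = np.array([False, False, False, True, True, True])
        np.testing.assert_array_equal(
            gate(pred, moving), np.array([0, 0, 0, 0, -1, 1])
        )

    def test_rule_table_has_six_rows_and_rest_dominates(self):
        rule = GatingRule()
        assert len(rule.table) == 6
        for (p, mv), final in rule.table:
            if not mv:
                assert final == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            gate(np.array([0, 1]), np.array([True]))
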