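import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repairnet.classify as classify
from repairnet import (NetworkGeneClassifier, SymmetricMinMaxScaler,
                       auc_score, compute_metrics, cross_validate,
                       load_config, train)
from repairnet.features import compute_rnr
from repairnet.synthetic import SyntheticSpec, generate


def brute_force_auc(scores, labels):
    """Fraction of (positive, negative) pairs ordered correctly, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestSymmetricMinMaxScaler:
    def test_maps_min_max_to_endpoints(self):
        X = np.array([[0.0], [5.0], [10.0]])
        out = SymmetricMinMaxScaler().fit_transform(X)
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        out = SymmetricMinMaxScaler().fit_transform(X)
        assert np.all(out[:, 0] == 0.0)
        assert np.allclose(out[:, 1], [-1.0, 0.0, 1.0])

    def test_out_of_range_test_values_may_exceed_band(self):
        scaler = SymmetricMinMaxScaler().fit([[0.0], [10.0]])
        assert scaler.transform([[20.0]])[0, 0] == pytest.approx(3.0)

    def test_sklearn_get_set_params(self):
        scaler = SymmetricMinMaxScaler()
        assert scaler.get_params() == {}
        # clone-compatible: refit on new data works
        scaler.fit([[1.0], [2.0]]).fit([[0.0], [4.0]])
        assert scaler.data_max_[0] == 4.0


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(tp=5, fp=0, tn=7, fn=0)
        assert (m["precision"], m["recall"], m["f1"]) == (1.0, 1.0, 1.0)

    def test_worked_confusion_counts(self):
        m = compute_metrics(tp=37, fp=13, tn=1000, fn=34)
        assert m["precision"] == pytest.approx(0.74)
        assert m["recall"] == pytest.approx(37 / 71)
        expected_f1 = 2 * m["precision"] * m["recall"] / (
            m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(expected_f1)

    def test_all_negative_prediction_flags_degenerate(self):
        m = compute_metrics(tp=0, fp=0, tn=10, fn=5)
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0
        assert "no_predicted_positives" in m["flags"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(tp=-1, fp=0, tn=0, fn=0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           tn=st.integers(0, 500), fn=st.integers(0, 500))
    def test_metric_identities_hold(self, tp, fp, tn, fn):
        m = compute_metrics(tp, fp, tn, fn)
        if tp + fp:
            assert m["precision"] == tp / (tp + fp)
        if tp + fn:
            assert m["recall"] == tp / (tp + fn)
        if m["precision"] + m["recall"]:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall"]
                / (m["precision"] + m["recall"]))
            assert (min(m["precision"], m["recall"]) - 1e-12 <= m["f1"]
                    <= max(m["precision"], m["recall"]) + 1e-12)
        assert (m["f1"] == 0.0) == (tp == 0)


class TestAUC:
    def test_all_ties_half(self):
        assert auc_score([1.0] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_hand_ranked_six_items(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 0, 1, 1, 0, 0]
        assert auc_score(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        # coarse grid forces ties
        scores = rng.integers(0, 6, n) / 5.0
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert auc_score(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.9], [1, 1])


def _toy_clusters(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2, 0.3, (n // 2, 3)),
                   rng.normal(2, 0.3, (n // 2, 3))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestClassifier:
    def test_separable_clusters_perfect_training_accuracy(self):
        X, y = _toy_clusters()
        model = train(X, y, seed=0)
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("kind", ["svm_rbf", "svm_poly",
                                      "decision_tree"])
    def test_all_model_kinds_produce_valid_posteriors(self, kind):
        X, y = _toy_clusters()
        model = train(X, y, kind=kind, seed=0)
        post = model.posterior(X)
        assert np.all((post >= 0) & (post <= 1))

    def test_unknown_kind_rejected(self):
        X, y = _toy_clusters()
        with pytest.raises(ValueError, match="unknown model kind"):
            train(X, y, kind="perceptron")

    def test_single_class_training_rejected(self):
        X, _ = _toy_clusters()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.zeros(len(X)))

    def test_posterior_monotone_in_decision_value(self):
        X, y = _toy_clusters(seed=1)
        model = train(X, y, seed=0)
        grid = np.linspace(-3, 3, 25)[:, None] * np.ones((1, 3))
        f = model.decision_function(grid)
        p = model.posterior(grid)
        order = np.argsort(f)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_deep_positive_scores_above_deep_negative(self):
        X, y = _toy_clusters(seed=2)
        model = train(X, y, seed=0)
        post = model.posterior(np.array([[2.0, 2.0, 2.0],
                                         [-2.0, -2.0, -2.0]]))
        assert post[0] > post[1]

    def test_uncalibrated_posterior_errors(self):
        X, y = _toy_clusters()
        model = NetworkGeneClassifier(calibration=None).fit(X, y)
        with pytest.raises(ValueError, match="without calibration"):
            model.posterior(X)

    def test_binning_calibrator_valid_and_monotone(self):
        X, y = _toy_clusters(n=200, seed=3)
        model = NetworkGeneClassifier(calibration="binning",
                                      n_bins=8).fit(X, y)
        f = model.decision_function(X)
        p = model.posterior(X)
        order = np.argsort(f)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_same_seed_same_predictions(self):
        X, y = _toy_clusters(n=60, seed=4)
        p1 = train(X, y, seed=7).posterior(X)
        p2 = train(X, y, seed=7).posterior(X)
        assert np.array_equal(p1, p2)

    def test_sklearn_params_roundtrip(self):
        model = NetworkGeneClassifier(kind="svm_poly", n_bins=12)
        params = model.get_params()
        assert params["kind"] == "svm_poly"
        clone = NetworkGeneClassifier().set_params(**params)
        assert clone.n_bins == 12


class TestCrossValidate:
    def test_report_counts_partition_samples(self, default_dataset):
        g, ann, _ = default_dataset
        rep = cross_validate(g, ann, seed=1)
        n_pos = len(ann.positives)
        pooled = rep.pooled
        assert pooled["tp"] + pooled["fn"] == n_pos
        assert pooled["tn"] + pooled["fp"] == g.number_of_nodes() - n_pos
        per_fold_pos = [f["tp"] + f["fn"] for f in rep.folds]
        assert sum(per_fold_pos) == n_pos
        # stratification: positives spread across all folds
        assert min(per_fold_pos) >= 1

    def test_shuffled_labels_auc_near_half(self):
        # no-signal null: random positive set on a null network
        from repairnet.synthetic import null_spec
        aucs = []
        for seed in range(4):
            g, ann, _ = generate(null_spec(seed=seed, n_background=800,
                                           n_planted=40, hold_out=0))
            aucs.append(cross_validate(g, ann, seed=seed).pooled["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_per_fold_policy_never_sees_test_labels(self, default_dataset,
                                                    monkeypatch):
        g, ann, _ = default_dataset
        calls = []
        real = compute_rnr

        def spy(network, positives):
            calls.append(set(positives))
            return real(network, positives)

        monkeypatch.setattr(classify, "compute_rnr", spy)
        cross_validate(g, ann, n_folds=5, seed=1, rnr_policy="per_fold")
        assert len(calls) == 5
        all_pos = set(ann.positives)
        for train_pos in calls:
            assert train_pos < all_pos  # strictly fewer than all positives
        # each positive is held out of exactly one fold's RNR computation
        for p in all_pos:
            assert sum(p not in c for c in calls) == 1

    def test_global_policy_uses_all_positives_once(self, default_dataset,
                                                   monkeypatch):
        g, ann, _ = default_dataset
        calls = []
        real = compute_rnr

        def spy(network, positives):
            calls.append(set(positives))
            return real(network, positives)

        monkeypatch.setattr(classify, "compute_rnr", spy)
        cross_validate(g, ann, seed=1, rnr_policy="global")
        assert calls == [set(ann.positives)]

    def test_too_few_positives_for_folds_errors(self):
        g, ann, _ = generate(SyntheticSpec(n_background=200, n_planted=4,
                                           hold_out=1, seed=0))
        with pytest.raises(ValueError, match="at least 5"):
            cross_validate(g, ann, n_folds=5, seed=0)

    def test_unknown_policy_rejected(self, default_dataset):
        g, ann, _ = default_dataset
        with pytest.raises(ValueError, match="rnr_policy"):
            cross_validate(g, ann, rnr_policy="sometimes")

    def test_report_json_roundtrip(self, tmp_path, default_dataset):
        import json
        g, ann, _ = default_dataset
        rep = cross_validate(g, ann, seed=1)
        path = tmp_path / "report.json"
        rep.to_json(path)
        data = json.loads(path.read_text())
        assert data["rnr_policy"] == "per_fold"
        assert data["pooled"]["tp"] == rep.pooled["tp"]
        assert len(data["folds"]) == 5


class TestConfig:
    def test_load_and_reject_unknown_keys(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("kind: svm_rbf\nn_folds: 5\nseed: 3\n")
        cfg = load_config(p)
        assert cfg == {"kind": "svm_rbf", "n_folds": 5, "seed": 3}
        p.write_text("knid: svm_rbf\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(p)
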