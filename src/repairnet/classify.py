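"""Classification of network nodes from topological features.

The model follows the standard LIBSVM workflow: features are scaled to
[-1, 1] on the training data, an SVM (RBF kernel by default; polynomial
kernel and a decision tree are the alternatives) is fitted with library
default hyperparameters, and raw decision values are converted to
posterior probabilities by a sigmoid (Platt) fit on the training decision
values — an equal-width binning calibrator is available as an alternative.

Evaluation is stratified k-fold cross-validation with precision, recall,
F1 from pooled confusion counts and AUC from the midrank Mann–Whitney
statistic on posteriors. Because the RNR feature depends on the positive
labels, the cross-validation protocol controls how it is computed:
``rnr_policy="per_fold"`` (default) recomputes RNR within each fold using
only training-fold positives — no test label ever reaches the features —
while ``"global"`` computes it once from all labels, reproducing the
common but leaky protocol of computing label-dependent features before
splitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FEATURE_COLUMNS, compute_rnr

MODEL_KINDS = ("svm_rbf", "svm_poly", "decision_tree")


class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Affine map of each feature to [-1, 1] fitted on training data.

    x -> 2 * (x - min) / (max - min) - 1, so the training minimum maps to
    -1 and the maximum to +1. A constant feature maps to 0. Transforming
    out-of-range test values may exceed [-1, 1]; that is the expected
    consequence of fitting on training data only and is left untouched.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, dtype=float)
        span = self.data_max_ - self.data_min_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.data_min_[nz]) / span[nz] - 1.0
        return out


def fit_scaling(X) -> SymmetricMinMaxScaler:
    """Fit the [-1, 1] scaling map on a feature matrix."""
    return SymmetricMinMaxScaler().fit(X)


def _platt_fit(decision_values, y) -> tuple:
    """Fit sigmoid parameters (A, B) so that P(pos|f) = 1/(1+exp(A*f+B)).

    Maximizes the regularized likelihood with the usual smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), which keep the fit finite
    even for separable training data.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * f + b
        # cross-entropy with targets t; log(1+e^z) via logaddexp for stability
        return float(np.sum(t * np.logaddexp(0.0, z)
                            + (1.0 - t) * np.logaddexp(0.0, -z)))

    res = optimize.minimize(nll, x0=np.array([-1.0, 0.0]), method="L-BFGS-B")
    return float(res.x[0]), float(res.x[1])


def _platt_apply(decision_values, a, b) -> np.ndarray:
    return special.expit(-(a * np.asarray(decision_values, float) + b))


class NetworkGeneClassifier(ClassifierMixin, BaseEstimator):
    """Scaled SVM (or decision tree) with calibrated posteriors.

    Parameters
    ----------
    kind : {"svm_rbf", "svm_poly", "decision_tree"}
        RBF-kernel SVM is the default; hyperparameters stay at library
        defaults (C = 1, gamma = 1/(d * Var)) unless overridden.
    calibration : {"sigmoid", "binning", None}
        How raw decision values become posterior probabilities. The
        sigmoid (Platt) fit on training decision values is the default;
        ``"binning"`` uses equal-width bins of the training decision
        values with monotonized empirical positive fractions. ``None``
        disables calibration; ``predict_proba`` then raises.
    n_bins : int
        Bin count for the binning calibrator.
    class_weight : passed through to the base model (None by default).
    params : dict, optional
        Extra keyword arguments for the underlying sklearn model.
    random_state : int
        Seed for the base model; the fit is deterministic given it.

    Attributes
    ----------
    scaler_ : SymmetricMinMaxScaler fitted on the training data only.
    base_ : the fitted sklearn model.
    calibration_params_ : sigmoid (A, B) or binning table.
    classes_ : array([0, 1]).
    """

    def __init__(self, kind: str = "svm_rbf", calibration: str = "sigmoid",
                 n_bins: int = 10, class_weight=None, params: dict = None,
                 random_state: int = 0):
        self.kind = kind
        self.calibration = calibration
        self.n_bins = n_bins
        self.class_weight = class_weight
        self.params = params
        self.random_state = random_state

    def _make_base(self):
        extra = dict(self.params or {})
        if self.kind == "svm_rbf":
            return SVC(kernel="rbf", class_weight=self.class_weight,
                       random_state=self.random_state, **extra)
        if self.kind == "svm_poly":
            return SVC(kernel="poly", class_weight=self.class_weight,
                       random_state=self.random_state, **extra)
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(class_weight=self.class_weight,
                                          random_state=self.random_state,
                                          **extra)
        raise ValueError(f"unknown model kind: {self.kind!r}; "
                         f"expected one of {MODEL_KINDS}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class; "
                             "both positives and negatives are required")
        self.n_features_in_ = X.shape[1]
        self.scaler_ = SymmetricMinMaxScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.base_ = self._make_base().fit(Xs, y)
        self._fit_calibration(Xs, y)
        return self

    def _raw_scores(self, Xs) -> np.ndarray:
        if isinstance(self.base_, SVC):
            return self.base_.decision_function(Xs)
        return self.base_.predict_proba(Xs)[:, 1]

    def _fit_calibration(self, Xs, y):
        if self.calibration is None:
            self.calibration_params_ = None
            return
        f = self._raw_scores(Xs)
        if self.calibration == "sigmoid":
            self.calibration_params_ = _platt_fit(f, y)
        elif self.calibration == "binning":
            edges = np.linspace(f.min(), f.max(), self.n_bins + 1)
            idx = np.clip(np.digitize(f, edges[1:-1]), 0, self.n_bins - 1)
            frac = np.full(self.n_bins, np.nan)
            weight = np.zeros(self.n_bins)
            for b in range(self.n_bins):
                mask = idx == b
                weight[b] = mask.sum()
                if weight[b]:
                    # Laplace smoothing keeps empty-ish bins off 0/1
                    frac[b] = ((y[mask] == 1).sum() + 1.0) / (weight[b] + 2.0)
            centers = (edges[:-1] + edges[1:]) / 2.0
            ok = weight > 0
            # pool-adjacent-violators: posterior must be monotone in the
            # decision value
            iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                     out_of_bounds="clip")
            iso.fit(centers[ok], frac[ok], sample_weight=weight[ok])
            self.calibration_params_ = iso
        else:
            raise ValueError(
                f"unknown calibration: {self.calibration!r}")

    def decision_function(self, X):
        check_is_fitted(self, "base_")
        X = check_array(X, dtype=float)
        return self._raw_scores(self.scaler_.transform(X))

    def predict_proba(self, X):
        check_is_fitted(self, "base_")
        if self.calibration is None:
            raise ValueError("model was trained without calibration; "
                             "posterior probabilities are unavailable")
        f = self.decision_function(X)
        if self.calibration == "sigmoid":
            a, b = self.calibration_params_
            p1 = _platt_apply(f, a, b)
        else:
            p1 = self.calibration_params_.predict(f)
        return np.column_stack([1.0 - p1, p1])

    def posterior(self, X) -> np.ndarray:
        """Calibrated probability of the positive class, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5):
        if self.calibration is None:
            return (self.decision_function(X) > 0).astype(int)
        return (self.posterior(X) >= threshold).astype(int)


def train(X, y, kind: str = "svm_rbf", seed: int = 0,
          **kwargs) -> NetworkGeneClassifier:
    """Fit a calibrated classifier; deterministic given the seed."""
    return NetworkGeneClassifier(kind=kind, random_state=seed,
                                 **kwargs).fit(X, y)


def auc_score(scores, labels) -> float:
    """AUC as the normalized midrank Mann–Whitney U statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly,
    ties counted 1/2; all-tied scores therefore give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(tp: int, fp: int, tn: int, fn: int,
                    scores=None) -> dict:
    """Precision, recall, F1 from confusion counts; AUC from scored pairs.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall). Degenerate denominators
    (no predicted positives, no actual positives, TP = 0) yield 0 with an
    explicit flag rather than NaN. ``scores`` is an iterable of
    (posterior, label) pairs used for the midrank AUC; omit it to skip
    AUC.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    flags = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("no_actual_positives")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        if tp == 0:
            flags.append("zero_tp")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    out = {"tp": int(tp), "fp": int(fp), "tn": int(tn), "fn": int(fn),
           "precision": precision, "recall": recall, "f1": f1,
           "flags": flags}
    if scores is not None:
        pairs = list(scores)
        out["auc"] = auc_score([s for s, _ in pairs],
                               [l for _, l in pairs])
    return out


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold and pooled confusion counts and
    metrics, plus the provenance needed to rerun it."""

    kind: str
    n_folds: int
    seed: int
    rnr_policy: str
    threshold: float
    folds: list = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    small_positive_set: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cross_validate(network, annotation, kind: str = "svm_rbf",
                   n_folds: int = 5, seed: int = 0,
                   rnr_policy: str = "per_fold", threshold: float = 0.5,
                   positives=None, calibration: str = "sigmoid",
                   class_weight=None, params: dict = None) -> EvaluationReport:
    """Stratified k-fold cross-validation of the node classifier.

    Each fold leaves out 1/k of the nodes as the test set. Degree and
    core number are label-free and computed once. Under
    ``rnr_policy="per_fold"`` the RNR of every node (train and test) is
    recomputed against the training fold's positives only, and scaling
    and calibration are fitted on the training fold — the honest
    protocol. ``"global"`` computes RNR once from all positive labels
    before splitting, which leaks test labels into the feature but
    matches the protocol commonly used with precomputed feature tables.

    ``positives`` overrides the annotation's positive set (used for
    per-pathway classifiers). Pooled metrics come from summed confusion
    counts; pooled AUC from all held-out posteriors.
    """
    from .features import compute_degrees, kcore_decomposition

    if rnr_policy not in ("per_fold", "global"):
        raise ValueError(f"unknown rnr_policy: {rnr_policy!r}")
    pos = set(positives) if positives is not None else set(
        annotation.positives)
    pos &= set(network.nodes)
    ids = sorted(network.nodes)
    y = np.array([1 if i in pos else 0 for i in ids])
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < n_folds or n_neg < n_folds:
        raise ValueError(
            f"need at least {n_folds} positives and negatives for "
            f"{n_folds}-fold stratified CV (have {n_pos} / {n_neg})")

    degrees = compute_degrees(network)
    cores = kcore_decomposition(network)
    base = np.array([[degrees[i], cores[i]] for i in ids], dtype=float)
    if rnr_policy == "global":
        rnr_all = compute_rnr(network, pos)
        global_col = np.array([rnr_all[i] for i in ids])

    report = EvaluationReport(kind=kind, n_folds=n_folds, seed=seed,
                              rnr_policy=rnr_policy, threshold=threshold,
                              small_positive_set=n_pos < 30)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled_scores: list = []
    totals = dict(tp=0, fp=0, tn=0, fn=0)
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(base, y)):
        if rnr_policy == "per_fold":
            train_pos = {ids[j] for j in train_idx if y[j] == 1}
            rnr_fold = compute_rnr(network, train_pos)
            col = np.array([rnr_fold[i] for i in ids])
        else:
            col = global_col
        X = np.column_stack([base, col])
        model = NetworkGeneClassifier(
            kind=kind, calibration=calibration, class_weight=class_weight,
            params=params, random_state=seed).fit(X[train_idx], y[train_idx])
        post = model.posterior(X[test_idx])
        pred = (post >= threshold).astype(int)
        yt = y[test_idx]
        tp = int(((pred == 1) & (yt == 1)).sum())
        fp = int(((pred == 1) & (yt == 0)).sum())
        tn = int(((pred == 0) & (yt == 0)).sum())
        fn = int(((pred == 0) & (yt == 1)).sum())
        fold_scores = list(zip(post.tolist(), yt.tolist()))
        metrics = compute_metrics(tp, fp, tn, fn, scores=fold_scores)
        metrics["fold"] = fold_no
        report.folds.append(metrics)
        pooled_scores.extend(fold_scores)
        for k, v in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn)):
            totals[k] += v
    report.pooled = compute_metrics(scores=pooled_scores, **totals)
    return report


def load_config(path) -> dict:
    """Read a YAML config for the classifier / CV stage.

    Recognized keys: ``kind``, ``calibration``, ``n_folds``, ``seed``,
    ``rnr_policy``, ``threshold``, ``class_weight``, ``params`` (passed
    to the underlying sklearn model). Unknown keys are rejected to catch
    typos.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"kind", "calibration", "n_folds", "seed", "rnr_policy",
               "threshold", "class_weight", "params", "n_bins"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
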