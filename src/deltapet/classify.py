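"""Leave-one-out cross-validated classification from region features.

Each subject is predicted by a model fitted on all other subjects, with
hyperparameter selection (a small fixed grid scored by stratified
internal cross-validation) restricted to the training fold.  Three model
kinds are supported: a linear logistic regression, a linear max-margin
classifier, and GentleBoost with regression-stump learners (Friedman's
adaptive-boosting variant, implemented with its exact weight updates).

Decision scores pooled across folds feed the ROC construction; scrambled
-label controls rerun the full LOOCV on permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from deltapet import roi
from deltapet.errors import FitError, InputError

__all__ = [
    "MODEL_KINDS",
    "FeatureTable",
    "LoocvOutcome",
    "ConfusionSummary",
    "RocCurve",
    "GentleBoostClassifier",
    "loocv_classify",
    "confusion_rates",
    "roc_from_scores",
    "scrambled_label_control",
]

MODEL_KINDS = ("linear-logistic", "max-margin", "gradient-boosting")

#: hyperparameter grids searched inside each training fold
_GRIDS = {
    "linear-logistic": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "max-margin": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "gradient-boosting": [{"n_estimators": n} for n in (10, 30, 100)],
}


class GentleBoostClassifier(BaseEstimator, ClassifierMixin):
    """GentleBoost with regression stumps.

    At each step a regression stump is fitted to the +/-1 labels by
    weighted least squares (leaf values are weighted label means), the
    additive model is updated with the stump output, and observation
    weights are multiplied by exp(-y * f_m(x)) and renormalized.
    Probabilities use the additive-logistic link 1 / (1 + exp(-2 F)).
    """

    def __init__(self, n_estimators: int = 50):
        self.n_estimators = n_estimators

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise FitError(f"GentleBoost needs 2 classes, got {len(self.classes_)}")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        n, _ = X.shape
        w = np.full(n, 1.0 / n)
        fvalue = np.zeros(n)
        self.stumps_ = []
        for _ in range(self.n_estimators):
            stump = self._fit_stump(X, ypm, w)
            fm = self._stump_predict(stump, X)
            fvalue += fm
            self.stumps_.append(stump)
            w = w * np.exp(-ypm * fm)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
        return self

    @staticmethod
    def _fit_stump(X, y, w):
        """Weighted-least-squares regression stump (feature, threshold, a, b)."""
        best = None
        best_sse = np.inf
        sw_y2 = float(np.sum(w * y * y))
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            ws = w[order]
            wys = (w * y)[order]
            cw = np.cumsum(ws)
            cwy = np.cumsum(wys)
            total_w, total_wy = cw[-1], cwy[-1]
            # candidate splits between distinct consecutive values
            distinct = np.flatnonzero(np.diff(xs) > 0)
            for k in distinct:
                wl, wr = cw[k], total_w - cw[k]
                if wl <= 0 or wr <= 0:
                    continue
                sl, sr = cwy[k], total_wy - cwy[k]
                sse = sw_y2 - sl * sl / wl - sr * sr / wr
                if sse < best_sse - 1e-15:
                    best_sse = sse
                    thr = 0.5 * (xs[k] + xs[k + 1])
                    best = (j, thr, sl / wl, sr / wr)
        if best is None:  # all feature values identical: constant learner
            total_w = float(np.sum(w))
            mean = float(np.sum(w * y) / total_w) if total_w > 0 else 0.0
            best = (0, -np.inf, mean, mean)
        return best

    @staticmethod
    def _stump_predict(stump, X):
        j, thr, a, b = stump
        return np.where(X[:, j] <= thr, a, b)

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        fvalue = np.zeros(X.shape[0])
        for stump in self.stumps_:
            fvalue += self._stump_predict(stump, X)
        return fvalue

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-2.0 * np.clip(self.decision_function(X), -250, 250)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0,
                        self.classes_[1], self.classes_[0])


@dataclass
class FeatureTable:
    """Per-subject region features plus binary group labels.

    ``frame`` is indexed by subject id with a ``group`` column and one
    column per region feature (fixed order).  The negative/positive class
    mapping is explicit so confusion rates are unambiguous.
    """

    frame: pd.DataFrame
    feature_columns: tuple[str, ...]
    negative_label: str
    positive_label: str

    def __post_init__(self) -> None:
        missing = [c for c in (*self.feature_columns, "group")
                   if c not in self.frame.columns]
        if missing:
            raise InputError(f"missing columns: {missing}")
        feats = self.frame[list(self.feature_columns)]
        if feats.isna().any().any():
            raise InputError("missing feature values")
        counts = self.frame["group"].value_counts()
        for label in (self.negative_label, self.positive_label):
            if counts.get(label, 0) < 2:
                raise InputError(f"need >= 2 subjects in class {label!r}")
        extra = set(self.frame["group"]) - {self.negative_label, self.positive_label}
        if extra:
            raise InputError(f"unknown group labels: {sorted(extra)}")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_columns)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @classmethod
    def from_delta_table(cls, delta_table: pd.DataFrame,
                         regions: tuple[str, ...] | None = None,
                         negative_label: str | None = None,
                         positive_label: str | None = None) -> "FeatureTable":
        """Per-subject region-mean delta-SUV features from a delta table."""
        if regions is None:
            regions = tuple(sorted(delta_table["region"].unique()))
        cols = {r: roi.subject_region_mean(delta_table, r) for r in regions}
        frame = pd.DataFrame(cols)
        groups = delta_table.drop_duplicates("subject_id").set_index("subject_id")["group"]
        frame["group"] = groups.reindex(frame.index)
        labels = sorted(frame["group"].unique())
        if negative_label is None:
            negative_label = labels[0]
        if positive_label is None:
            positive_label = [l for l in labels if l != negative_label][0]
        return cls(frame=frame, feature_columns=tuple(regions),
                   negative_label=negative_label, positive_label=positive_label)

    def with_labels(self, y: np.ndarray) -> "FeatureTable":
        frame = self.frame.copy()
        frame["group"] = y
        return FeatureTable(frame=frame, feature_columns=self.feature_columns,
                            negative_label=self.negative_label,
                            positive_label=self.positive_label)


@dataclass
class LoocvOutcome:
    """One prediction and score per subject, from leave-one-out folds."""

    frame: pd.DataFrame  # columns: true, predicted, score; index subject_id
    model_kind: str
    positive_label: str
    negative_label: str
    seed: int

    def to_dict(self) -> dict:
        return {"model_kind": self.model_kind, "seed": self.seed,
                "positive_label": self.positive_label,
                "negative_label": self.negative_label,
                "predictions": self.frame.reset_index().to_dict("records")}


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion rates as percentages of each true class."""

    tn_rate: float
    fp_rate: float
    fn_rate: float
    tp_rate: float
    counts: dict = field(default_factory=dict)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    variant: str = "real"


def _make_estimator(model_kind: str, params: dict, seed: int):
    if model_kind == "linear-logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if model_kind == "max-margin":
        return SVC(kernel="linear", random_state=seed, **params)
    if model_kind == "gradient-boosting":
        return GentleBoostClassifier(**params)
    raise InputError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")


def _standardize(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def _fit_fold(X_train, y_train, X_test, model_kind: str, seed: int,
              positive_label) -> tuple[np.ndarray, np.ndarray]:
    """Grid-select, fit on the full training fold, score the held-out rows."""
    if len(np.unique(y_train)) < 2:
        raise FitError("training fold is missing a class")
    if model_kind in ("linear-logistic", "max-margin"):
        X_train, X_test = _standardize(X_train, X_test)
    grid = _GRIDS[model_kind]
    best_params, best_acc = grid[0], -np.inf
    if len(grid) > 1:
        min_class = np.unique(y_train, return_counts=True)[1].min()
        n_splits = int(min(3, min_class))
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for params in grid:
                accs = []
                for tr, va in cv.split(X_train, y_train):
                    est = _make_estimator(model_kind, params, seed)
                    est.fit(X_train[tr], y_train[tr])
                    accs.append(np.mean(est.predict(X_train[va]) == y_train[va]))
                acc = float(np.mean(accs))
                if acc > best_acc + 1e-12:
                    best_acc, best_params = acc, params
    est = _make_estimator(model_kind, best_params, seed)
    est.fit(X_train, y_train)
    pred = est.predict(X_test)
    if model_kind == "max-margin":
        score = est.decision_function(X_test)
        if est.classes_[1] != positive_label:
            score = -score
    else:
        pos_idx = int(np.flatnonzero(est.classes_ == positive_label)[0])
        score = est.predict_proba(X_test)[:, pos_idx]
    return pred, np.asarray(score, dtype=float)


def loocv_classify(features: FeatureTable, model_kind: str = "linear-logistic",
                   seed: int = 0) -> LoocvOutcome:
    """Predict every subject from a model fitted without that subject.

    Hyperparameters are selected inside each training fold; scores are
    class-probabilities of the positive class (signed margins for the
    max-margin model), comparable across folds.
    """
    if model_kind not in MODEL_KINDS:
        raise InputError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    X, y, ids = features.X, features.y, features.subject_ids
    rows = []
    for i in range(len(ids)):
        keep = np.arange(len(ids)) != i
        pred, score = _fit_fold(X[keep], y[keep], X[i:i + 1], model_kind, seed,
                                features.positive_label)
        rows.append({"subject_id": ids[i], "true": y[i],
                     "predicted": pred[0], "score": float(score[0])})
    frame = pd.DataFrame(rows).set_index("subject_id")
    return LoocvOutcome(frame=frame, model_kind=model_kind,
                        positive_label=features.positive_label,
                        negative_label=features.negative_label, seed=seed)


def confusion_rates(outcome: LoocvOutcome) -> ConfusionSummary:
    """Percent rates over each true class (negative: TN/FP, positive: FN/TP)."""
    t = outcome.frame["true"]
    p = outcome.frame["predicted"]
    neg, pos = outcome.negative_label, outcome.positive_label
    tn = int(((t == neg) & (p == neg)).sum())
    fp = int(((t == neg) & (p == pos)).sum())
    fn = int(((t == pos) & (p == neg)).sum())
    tp = int(((t == pos) & (p == pos)).sum())
    n_neg, n_pos = tn + fp, fn + tp
    if n_neg == 0 or n_pos == 0:
        raise InputError("need at least one subject per true class")
    return ConfusionSummary(
        tn_rate=100.0 * tn / n_neg, fp_rate=100.0 * fp / n_neg,
        fn_rate=100.0 * fn / n_pos, tp_rate=100.0 * tp / n_pos,
        counts={"tn": tn, "fp": fp, "fn": fn, "tp": tp})


def roc_from_scores(outcome: LoocvOutcome, variant: str = "real") -> RocCurve:
    """ROC over pooled LOOCV scores; AUC by the trapezoid rule."""
    y = (outcome.frame["true"] == outcome.positive_label).to_numpy()
    scores = outcome.frame["score"].to_numpy()
    fpr, tpr, _ = sklearn.metrics.roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(sklearn.metrics.auc(fpr, tpr)),
                    variant=variant)


def scrambled_label_control(features: FeatureTable, model_kind: str,
                            n_reps: int, seed: int = 0) -> np.ndarray:
    """Null AUC distribution from label-scrambled LOOCV reruns.

    Per repetition the class labels are permuted once across subjects and
    the full LOOCV (including per-fold hyperparameter selection) is rerun
    on the scrambled table.  Each repetition's pooled scores are evaluated
    against the *true* labels: a scrambled-trained model carries no real
    class information, so these AUCs fluctuate around 0.5.  (Scoring
    against the permuted labels instead would inherit the well-known
    LOOCV anti-correlation bias and sit systematically below 0.5.)
    """
    if n_reps < 0:
        raise InputError("n_reps must be >= 0")
    rng = np.random.default_rng(seed)
    y_true = (features.y == features.positive_label)
    aucs = []
    for _ in range(n_reps):
        perm = rng.permutation(len(features.frame))
        scrambled = features.with_labels(features.y[perm])
        rep_seed = int(rng.integers(0, 2**31 - 1))
        outcome = loocv_classify(scrambled, model_kind, seed=rep_seed)
        scores = outcome.frame.loc[features.frame.index, "score"].to_numpy()
        fpr, tpr, _ = sklearn.metrics.roc_curve(y_true, scores,
                                                drop_intermediate=False)
        aucs.append(float(sklearn.metrics.auc(fpr, tpr)))
    return np.asarray(aucs)
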