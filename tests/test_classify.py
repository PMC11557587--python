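import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from deltapet import classify
from deltapet.classify import (
    FeatureTable,
    GentleBoostClassifier,
    confusion_rates,
    loocv_classify,
    roc_from_scores,
    scrambled_label_control,
)
from deltapet.errors import InputError


def make_features(X, y, subject_ids=None):
    X = np.asarray(X, dtype=float)
    cols = [f"f{j}" for j in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols)
    frame["group"] = y
    frame.index = subject_ids or [f"s{i}" for i in range(len(frame))]
    frame.index.name = "subject_id"
    return FeatureTable(frame=frame, feature_columns=tuple(cols),
                        negative_label="neg", positive_label="pos")


def separable_features(rng, n_per_class=12, n_features=8, gap=5.0):
    X_neg = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X_pos = rng.normal(gap, 1.0, (n_per_class, n_features))
    X = np.vstack([X_neg, X_pos])
    y = ["neg"] * n_per_class + ["pos"] * n_per_class
    return make_features(X, y)


class TestGentleBoost:
    def test_stump_matches_weighted_ls_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.choice([-1.0, 1.0], 30)
        w = rng.uniform(0.1, 1.0, 30)
        w /= w.sum()
        stump = GentleBoostClassifier._fit_stump(X, y, w)
        # brute-force oracle over every feature and threshold midpoint
        best_sse = np.inf
        for j in range(3):
            xs = np.unique(X[:, j])
            for thr in (xs[:-1] + xs[1:]) / 2:
                left = X[:, j] <= thr
                a = np.average(y[left], weights=w[left])
                b = np.average(y[~left], weights=w[~left])
                pred = np.where(left, a, b)
                sse = float(np.sum(w * (y - pred) ** 2))
                if sse < best_sse:
                    best_sse = sse
        j, thr, a, b = stump
        pred = np.where(X[:, j] <= thr, a, b)
        assert np.sum(w * (y - pred) ** 2) == pytest.approx(best_sse, abs=1e-10)

    def test_separable_fit(self, rng):
        X = np.vstack([rng.normal(-3, 0.5, (20, 2)), rng.normal(3, 0.5, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = GentleBoostClassifier(n_estimators=20).fit(X, y)
        assert (model.predict(X) == y).all()
        proba = model.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_constant_features_degenerate(self):
        X = np.ones((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        model = GentleBoostClassifier(n_estimators=5).fit(X, y)
        assert len(model.predict(X)) == 10


class TestFeatureTable:
    def test_missing_values_rejected(self):
        frame = pd.DataFrame({"f0": [1.0, np.nan, 2.0, 3.0],
                              "group": ["neg", "neg", "pos", "pos"]})
        with pytest.raises(InputError):
            FeatureTable(frame=frame, feature_columns=("f0",),
                         negative_label="neg", positive_label="pos")

    def test_single_subject_class_rejected(self):
        frame = pd.DataFrame({"f0": [1.0, 2.0, 3.0],
                              "group": ["neg", "pos", "pos"]})
        with pytest.raises(InputError):
            FeatureTable(frame=frame, feature_columns=("f0",),
                         negative_label="neg", positive_label="pos")

    def test_from_delta_table(self, small_delta_table):
        table = FeatureTable.from_delta_table(small_delta_table)
        assert table.negative_label == "CON"
        assert table.positive_label == "LS"
        assert len(table.feature_columns) == 8
        assert len(table.frame) == 7


class TestLoocv:
    def test_separated_clusters_perfect(self, rng):
        features = separable_features(rng)
        outcome = loocv_classify(features, "linear-logistic", seed=0)
        rates = confusion_rates(outcome)
        assert rates.tp_rate == 100.0
        assert rates.tn_rate == 100.0

    def test_uninformative_features_no_skill(self, rng):
        X = np.ones((20, 4))
        y = ["neg"] * 8 + ["pos"] * 12
        outcome = loocv_classify(make_features(X, y), "linear-logistic", seed=0)
        accuracy = (outcome.frame["true"] == outcome.frame["predicted"]).mean()
        assert accuracy <= 12 / 20 + 1e-9

    @pytest.mark.parametrize("kind", classify.MODEL_KINDS)
    def test_all_model_kinds_run(self, rng, kind):
        features = separable_features(rng, n_per_class=6)
        outcome = loocv_classify(features, kind, seed=1)
        assert len(outcome.frame) == 12
        assert outcome.frame["score"].notna().all()

    def test_matches_brute_force_fold_oracle(self, rng):
        # independent re-implementation of the documented per-fold recipe
        X = rng.normal(size=(6, 2))
        X[3:] += 1.0
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        features = make_features(X, y)
        outcome = loocv_classify(features, "linear-logistic", seed=0)
        grid = (0.01, 0.1, 1.0, 10.0)
        for i in range(6):
            keep = np.arange(6) != i
            Xtr, ytr = X[keep], y[keep]
            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd[sd == 0] = 1.0
            Xtr_s = (Xtr - mu) / sd
            Xte_s = (X[i:i + 1] - mu) / sd
            cv = StratifiedKFold(2, shuffle=True, random_state=0)
            best_c, best_acc = grid[0], -np.inf
            for c in grid:
                accs = [LogisticRegression(C=c, max_iter=2000, random_state=0)
                        .fit(Xtr_s[tr], ytr[tr]).score(Xtr_s[va], ytr[va])
                        for tr, va in cv.split(Xtr_s, ytr)]
                if np.mean(accs) > best_acc + 1e-12:
                    best_acc, best_c = np.mean(accs), c
            model = LogisticRegression(C=best_c, max_iter=2000, random_state=0)
            model.fit(Xtr_s, ytr)
            assert outcome.frame["predicted"].iloc[i] == model.predict(Xte_s)[0]

    def test_no_leakage(self, rng):
        # fold i is fitted without subject i: flipping subject i's label
        # (everything else fixed) cannot change subject i's own score
        features = separable_features(rng, n_per_class=4, gap=1.0)
        outcome_full = loocv_classify(features, "linear-logistic", seed=3)
        flipped_frame = features.frame.copy()
        target = flipped_frame.index[0]
        flipped_frame.loc[target, "group"] = "pos"  # was neg
        flipped = FeatureTable(frame=flipped_frame,
                               feature_columns=features.feature_columns,
                               negative_label="neg", positive_label="pos")
        outcome_flipped = loocv_classify(flipped, "linear-logistic", seed=3)
        assert outcome_flipped.frame.loc[target, "score"] == \
            outcome_full.frame.loc[target, "score"]
        assert outcome_flipped.frame.loc[target, "predicted"] == \
            outcome_full.frame.loc[target, "predicted"]

    def test_determinism(self, rng):
        features = separable_features(rng, n_per_class=5, gap=1.0)
        a = loocv_classify(features, "linear-logistic", seed=4)
        b = loocv_classify(features, "linear-logistic", seed=4)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestConfusion:
    def test_seven_of_nine_true_negatives(self):
        frame = pd.DataFrame({
            "true": ["neg"] * 9 + ["pos"] * 15,
            "predicted": ["neg"] * 7 + ["pos"] * 2 + ["pos"] * 15,
            "score": np.linspace(0, 1, 24)})
        outcome = classify.LoocvOutcome(frame=frame, model_kind="linear-logistic",
                                        positive_label="pos",
                                        negative_label="neg", seed=0)
        rates = confusion_rates(outcome)
        assert round(rates.tn_rate, 1) == 77.8
        assert round(rates.fp_rate, 1) == 22.2
        assert rates.tp_rate == 100.0
        assert rates.fn_rate == 0.0

    def test_all_correct(self):
        frame = pd.DataFrame({"true": ["neg", "neg", "pos", "pos"],
                              "predicted": ["neg", "neg", "pos", "pos"],
                              "score": [0.1, 0.2, 0.8, 0.9]})
        outcome = classify.LoocvOutcome(frame=frame, model_kind="linear-logistic",
                                        positive_label="pos",
                                        negative_label="neg", seed=0)
        rates = confusion_rates(outcome)
        assert (rates.tn_rate, rates.fp_rate, rates.fn_rate, rates.tp_rate) == \
            (100.0, 0.0, 0.0, 100.0)

    def test_direct_count_oracle(self, rng):
        true = rng.choice(["neg", "pos"], 30)
        true[:2] = ["neg", "pos"]  # both classes present
        pred = rng.choice(["neg", "pos"], 30)
        frame = pd.DataFrame({"true": true, "predicted": pred,
                              "score": rng.random(30)})
        outcome = classify.LoocvOutcome(frame=frame, model_kind="linear-logistic",
                                        positive_label="pos",
                                        negative_label="neg", seed=0)
        rates = confusion_rates(outcome)
        tn = sum((t == "neg") and (p == "neg") for t, p in zip(true, pred))
        assert rates.counts["tn"] == tn


class TestRoc:
    @staticmethod
    def outcome_from_scores(y, scores):
        frame = pd.DataFrame({"true": y, "predicted": y, "score": scores})
        return classify.LoocvOutcome(frame=frame, model_kind="linear-logistic",
                                     positive_label="pos", negative_label="neg",
                                     seed=0)

    def test_perfect_ranking(self):
        curve = roc_from_scores(self.outcome_from_scores(
            ["neg"] * 5 + ["pos"] * 5, np.arange(10, dtype=float)))
        assert curve.auc == 1.0

    def test_constant_scores(self):
        curve = roc_from_scores(self.outcome_from_scores(
            ["neg", "pos"] * 5, np.ones(10)))
        assert curve.auc == pytest.approx(0.5)

    def test_endpoints(self, rng):
        curve = roc_from_scores(self.outcome_from_scores(
            rng.choice(["neg", "pos"], 12).tolist() + ["neg", "pos"],
            rng.random(14)))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    def test_concordance_oracle(self, rng):
        y = np.array(["neg"] * 5 + ["pos"] * 5)
        scores = rng.random(10)
        curve = roc_from_scores(self.outcome_from_scores(y, scores))
        pos, neg = scores[5:], scores[:5]
        conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert curve.auc == pytest.approx(conc, abs=1e-12)

    def test_label_swap_antisymmetry(self, rng):
        y = ["neg"] * 6 + ["pos"] * 6
        scores = rng.random(12)
        a = roc_from_scores(self.outcome_from_scores(y, scores))
        flipped = self.outcome_from_scores(
            ["pos" if v == "neg" else "neg" for v in y], scores)
        b = roc_from_scores(flipped)
        assert a.auc == pytest.approx(1.0 - b.auc, abs=1e-12)


class TestScrambled:
    def test_zero_reps_empty(self, rng):
        features = separable_features(rng, n_per_class=4)
        assert scrambled_label_control(features, "linear-logistic", 0).size == 0

    def test_fixed_seed_reproducible(self, rng):
        features = separable_features(rng, n_per_class=4, gap=1.0)
        a = scrambled_label_control(features, "linear-logistic", 3, seed=5)
        b = scrambled_label_control(features, "linear-logistic", 3, seed=5)
        assert np.array_equal(a, b)

    def test_informative_vs_scrambled(self, rng):
        features = separable_features(rng, n_per_class=8)
        real = roc_from_scores(loocv_classify(features, "linear-logistic", 0)).auc
        null = scrambled_label_control(features, "linear-logistic", 10, seed=0)
        assert real > 0.9
        assert 0.2 < null.mean() < 0.8
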