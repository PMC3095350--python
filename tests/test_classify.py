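"""Naive Bayes fitting/posteriors, AUC, cross-validation and information gain."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nagnag import (
    compute_posterior,
    compute_roc_auc,
    cross_validate,
    fit_naive_bayes,
    predict_class,
    predict_proba,
    rank_information_gain,
    transfer_predict,
)
from nagnag.classify import CLASSES, NaiveBayesModel, predict_log_proba
from nagnag.features import REDUCED_FEATURES


def toy_frame(letters, feature="n1"):
    return pd.DataFrame({feature: list(letters)})


def make_training(n_per_class=4):
    """Perfectly separable toy set: the letter of n1 encodes the class."""
    letter = {"E": "A", "I": "C", "EI": "G"}
    rows, y = [], []
    for c in CLASSES:
        for _ in range(n_per_class):
            rows.append({"n1": letter[c]})
            y.append(c)
    return pd.DataFrame(rows), y


class TestFit:
    def test_balanced_priors(self):
        X, y = make_training(5)
        model = fit_naive_bayes(X, y)
        assert np.allclose([math.exp(model.log_prior[c]) for c in CLASSES], 1 / 3)

    def test_categorical_tables_match_hand_counts(self):
        X = toy_frame("AACGG")
        y = ["E", "E", "I", "EI", "EI"]
        model = fit_naive_bayes(X, y, alpha=1.0)
        t = model.cat_prob["n1"]
        # class E: 2 of 2 are A -> (2+1)/(2+4); C appears 0 times -> 1/6
        assert math.isclose(t["E"]["A"], 3 / 6)
        assert math.isclose(t["E"]["C"], 1 / 6)
        # class I: single C -> (1+1)/(1+4)
        assert math.isclose(t["I"]["C"], 2 / 5)
        # class EI: two G -> (2+1)/(2+4)
        assert math.isclose(t["EI"]["G"], 3 / 6)
        for c in CLASSES:
            assert math.isclose(sum(t[c].values()), 1.0)
            assert min(t[c].values()) > 0  # smoothing keeps everything positive

    def test_missing_class_is_hard_error(self):
        X = toy_frame("AACC")
        with pytest.raises(ValueError, match="EI"):
            fit_naive_bayes(X, ["E", "E", "I", "I"])

    def test_constant_numeric_feature_hits_variance_floor(self):
        X = pd.DataFrame({"n1": list("ACGACG"), "y_content": [7.0] * 6})
        y = ["E", "I", "EI"] * 2
        model = fit_naive_bayes(X, y, var_floor=1e-9)
        for c in CLASSES:
            assert model.gauss["y_content"][c][1] == 1e-9
        # and posteriors stay finite
        proba = predict_proba(model, X)
        assert np.isfinite(proba.to_numpy()).all()


class TestPosterior:
    def test_uninformative_features_return_priors(self):
        # every class sees only letter A: with smoothing off the feature
        # term is 1 for every class and cancels exactly
        X = toy_frame("A" * 10)
        y = ["E"] * 5 + ["I"] * 3 + ["EI"] * 2
        model = fit_naive_bayes(X, y, alpha=0.0)
        post = compute_posterior(model, {"n1": "A"})
        assert math.isclose(post.p_E, 0.5, abs_tol=1e-12)
        assert math.isclose(post.p_I, 0.3, abs_tol=1e-12)
        assert math.isclose(post.p_EI, 0.2, abs_tol=1e-12)

    def test_hand_bayes_single_feature(self):
        """Posterior equals the hand-worked Bayes computation."""
        X = toy_frame("AACGG")
        y = ["E", "E", "I", "EI", "EI"]
        model = fit_naive_bayes(X, y, alpha=1.0)
        post = compute_posterior(model, {"n1": "A"})
        # joint = prior * P(A|class)
        jE = (2 / 5) * (3 / 6)
        jI = (1 / 5) * (1 / 5)
        jEI = (2 / 5) * (1 / 6)
        z = jE + jI + jEI
        assert math.isclose(post.p_E, jE / z)
        assert math.isclose(post.p_I, jI / z)
        assert math.isclose(post.p_EI, jEI / z)

    def test_posteriors_normalise_for_random_vectors(self):
        rng = np.random.default_rng(0)
        X, y = make_training(6)
        X["y_content"] = rng.integers(0, 21, len(X)).astype(float)
        model = fit_naive_bayes(X, y)
        probe = pd.DataFrame({
            "n1": rng.choice(list("ACGT"), 40),
            "y_content": rng.integers(0, 21, 40).astype(float),
        })
        proba = predict_proba(model, probe).to_numpy()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_feature_terms_are_dropped(self):
        X, y = make_training(5)
        X["y_content"] = [float(i) for i in range(len(X))]
        model = fit_naive_bayes(X, y)
        full = compute_posterior(model, {"n1": "A", "y_content": np.nan})
        cat_only = compute_posterior(model, {"n1": "A"})
        assert math.isclose(full.p_E, cat_only.p_E)

    def test_agrees_with_sklearn_categorical_nb(self):
        """Independent cross-check on a categorical-only model."""
        from sklearn.naive_bayes import CategoricalNB

        rng = np.random.default_rng(3)
        n = 300
        X = pd.DataFrame({
            "n1": rng.choice(list("ACGT"), n),
            "n2": rng.choice(list("ACGT"), n, p=[0.1, 0.4, 0.2, 0.3]),
        })
        y = rng.choice(list(CLASSES), n)
        model = fit_naive_bayes(X, y, alpha=1.0)
        mine = predict_proba(model, X).to_numpy()
        enc = X.apply(lambda col: col.map({b: i for i, b in enumerate("ACGT")}))
        sk = CategoricalNB(alpha=1.0, min_categories=4).fit(enc, y)
        theirs = sk.predict_proba(enc)
        order = [list(sk.classes_).index(c) for c in CLASSES]
        assert np.allclose(mine, theirs[:, order], atol=1e-9)


class TestPredictClass:
    @pytest.mark.parametrize("proba,expected", [
        ((0.1, 0.1, 0.8), "EI"),
        ((1 / 3, 1 / 3, 1 / 3), "E"),  # documented tie order E > I > EI
        ((0.05, 0.05, 0.9), "EI"),
        ((0.4, 0.4, 0.2), "E"),
    ])
    def test_argmax_with_tie_order(self, proba, expected):
        assert predict_class(proba) == expected

    def test_single_feature_decision_matches_enumeration(self):
        """predict_class agrees with exhaustive Bayes-rule enumeration."""
        X = toy_frame("AAACCGGT")
        y = ["E", "E", "E", "I", "I", "EI", "EI", "EI"]
        model = fit_naive_bayes(X, y)
        prior = {c: math.exp(model.log_prior[c]) for c in CLASSES}
        for letter in "ACGT":
            joint = [prior[c] * model.cat_prob["n1"][c][letter] for c in CLASSES]
            expected = CLASSES[int(np.argmax(joint))]
            post = compute_posterior(model, {"n1": letter})
            assert predict_class(post) == expected


class TestAuc:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.9, 0.4], [0.5, 0.1], 0.75),  # 3 of 4 positive-negative pairs win
    ])
    def test_known_values(self, pos, neg, expected):
        scores = pos + neg
        labels = [1] * len(pos) + [0] * len(neg)
        assert compute_roc_auc(scores, labels) == pytest.approx(expected)

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            compute_roc_auc([0.1, 0.2], [1, 1])

    def test_equals_pair_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.random(60), 1)  # rounding forces ties
        labels = rng.random(60) < 0.4
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p, q in itertools.product(pos, neg))
        oracle = wins / (len(pos) * len(neg))
        assert compute_roc_auc(scores, labels) == pytest.approx(oracle)

    def test_equals_trapezoidal_area_under_empirical_roc(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(11)
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200)) > 0.5
        fpr, tpr, _ = roc_curve(labels.astype(int), scores)
        assert compute_roc_auc(scores, labels) == pytest.approx(np.trapezoid(tpr, fpr))


class TestCrossValidate:
    def test_perfectly_separable_data_gives_auc_one(self):
        X, y = make_training(12)
        for folds in (2, 5, 10):
            cv = cross_validate(X, y, folds=folds, seed=0)
            assert all(v == pytest.approx(1.0) for v in cv.auc.values())
        loo = cross_validate(X, y, loo=True)
        assert all(v == pytest.approx(1.0) for v in loo.auc.values())

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        n = 900
        X = pd.DataFrame({
            "n1": rng.choice(list("ACGT"), n),
            "n2": rng.choice(list("ACGT"), n),
            "y_content": rng.integers(0, 21, n).astype(float),
        })
        y = rng.choice(list(CLASSES), n)
        cv = cross_validate(X, y, folds=5, seed=1)
        for v in cv.auc.values():
            assert abs(v - 0.5) < 0.08

    def test_too_few_class_members_suggests_smaller_k(self):
        X, y = make_training(4)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(X, y, folds=5, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        n = 120
        X = pd.DataFrame({"n1": rng.choice(list("ACGT"), n)})
        y = rng.choice(list(CLASSES), n)
        a = cross_validate(X, y, folds=4, seed=9)
        b = cross_validate(X, y, folds=4, seed=9)
        assert a.auc == b.auc


class TestInformationGain:
    def test_feature_identical_to_balanced_binary_label(self):
        X = toy_frame("AACC")
        y = ["E", "E", "I", "I"]
        r = rank_information_gain(X, y)
        assert r.class_entropy == pytest.approx(1.0)
        assert r.gains["n1"] == pytest.approx(1.0)

    def test_constant_features_have_zero_gain(self):
        X = pd.DataFrame({"n1": list("AAAA"), "y_content": [3.0] * 4})
        r = rank_information_gain(X, ["E", "E", "I", "I"])
        assert r.gains["n1"] == pytest.approx(0.0)
        assert r.gains["y_content"] == pytest.approx(0.0)

    def test_hand_worked_example(self):
        """Labels (E,E,I,I) with feature (A,A,A,C): IG = 1 - 0.75*H(1/3)."""
        r = rank_information_gain(toy_frame("AAAC"), ["E", "E", "I", "I"])
        h13 = -(1 / 3) * math.log2(1 / 3) - (2 / 3) * math.log2(2 / 3)
        assert r.gains["n1"] == pytest.approx(1 - 0.75 * h13)
        assert r.gains["n1"] == pytest.approx(0.3113, abs=1e-4)

    def test_bounds_and_letter_relabel_invariance(self):
        rng = np.random.default_rng(2)
        n = 200
        X = pd.DataFrame({
            "n1": rng.choice(list("ACGT"), n),
            "y_content": rng.integers(0, 21, n).astype(float),
        })
        y = rng.choice(list(CLASSES), n)
        r = rank_information_gain(X, y)
        for g in r.gains.to_numpy():
            assert -1e-12 <= g <= r.class_entropy + 1e-12
        relabel = {"A": "T", "C": "G", "G": "A", "T": "C"}
        X2 = X.assign(n1=X["n1"].map(relabel))
        r2 = rank_information_gain(X2, y)
        assert r2.gains["n1"] == pytest.approx(r.gains["n1"])


class TestTransfer:
    def _fitted(self):
        rng = np.random.default_rng(4)
        n = 240
        cols = {f: rng.choice(list("ACGT"), n) for f in REDUCED_FEATURES}
        cols["exon_m1"] = rng.choice(list("ACGT"), n)
        X = pd.DataFrame(cols)
        y = rng.choice(list(CLASSES), n)
        return fit_naive_bayes(X, y), X

    def test_same_dataset_equals_in_domain_posteriors(self):
        model, X = self._fitted()
        a = transfer_predict(model, X).to_numpy()
        b = predict_proba(model, X).to_numpy()
        assert np.allclose(a, b)

    def test_reduced_view_uses_exactly_five_predictors(self):
        model, X = self._fitted()
        reduced = transfer_predict(model, X, reduced=True)
        # scrambling a non-reduced feature must not change reduced posteriors
        X2 = X.copy()
        X2["exon_m1"] = "T"
        assert np.allclose(reduced.to_numpy(),
                           transfer_predict(model, X2, reduced=True).to_numpy())

    def test_schema_mismatch_is_hard_error(self):
        model, X = self._fitted()
        with pytest.raises(ValueError, match="missing"):
            transfer_predict(model, X.drop(columns=["n1"]))

    def test_cross_generator_transfer_beats_shuffled_baseline(self):
        """Train on one simulated cohort, test on another sharing the signal."""
        from nagnag.features import acceptor_window, extract_features
        from nagnag import train_acceptor_pwm
        from nagnag.simulate import SimConfig, sample_labeled_contexts

        def cohort(seed):
            contexts, labels = sample_labeled_contexts(SimConfig(seed=seed), 150)
            pwm = train_acceptor_pwm([acceptor_window(c, "distal") for c in contexts])

            class Stub:
                def __init__(self, c):
                    self.site_id, self.motif = c.site_id, c.motif

            frame, _ = extract_features([Stub(c) for c in contexts],
                                        {c.site_id: c for c in contexts}, pwm)
            y = pd.Series({c.site_id: labels[c.site_id] for c in contexts})
            return frame, y

        Xa, ya = cohort(21)
        Xb, yb = cohort(22)
        model = fit_naive_bayes(Xa, ya)
        proba = transfer_predict(model, Xb)
        auc_ei = compute_roc_auc(proba["p_EI"], (yb == "EI"))
        rng = np.random.default_rng(0)
        shuffled = compute_roc_auc(proba["p_EI"],
                                   rng.permutation((yb == "EI").to_numpy()))
        assert auc_ei > 0.85
        assert auc_ei > shuffled + 0.2

    def test_model_json_round_trip(self, tmp_path):
        model, X = self._fitted()
        model.to_json(tmp_path / "m.json")
        back = NaiveBayesModel.from_json(tmp_path / "m.json")
        assert np.allclose(predict_proba(back, X).to_numpy(),
                           predict_proba(model, X).to_numpy())


def test_log_space_stability_on_31_features():
    """Posterior stays normalised with all 31 features and extreme values."""
    rng = np.random.default_rng(8)
    from nagnag.features import FEATURE_NAMES, NUMERIC_FEATURES

    n = 90
    cols = {}
    for f in FEATURE_NAMES:
        if f in NUMERIC_FEATURES:
            cols[f] = rng.normal(0, 50, n)
        else:
            cols[f] = rng.choice(list("ACGT"), n)
    X = pd.DataFrame(cols)
    y = rng.choice(list(CLASSES), n)
    model = fit_naive_bayes(X, y)
    lp = predict_log_proba(model, X)
    assert np.isfinite(lp).all()
    assert np.allclose(np.exp(lp).sum(axis=1), 1.0, atol=1e-9)
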