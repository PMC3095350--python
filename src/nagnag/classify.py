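"""Three-class Naïve Bayes prediction of tandem-acceptor splicing outcome.

The model assigns posterior probabilities P(E), P(I), P(EI) to a site
from its sequence features alone: categorical (nucleotide) features get
Laplace-smoothed class-conditional tables over A/C/G/T, numeric features
(Y-content and the two acceptor scores) class-conditional Gaussians with
a variance floor.  Evaluation uses seeded stratified cross-validation
with one-vs-rest rank-based (Mann-Whitney) AUC per class, and features
are ranked by information gain H(Class) - H(Class|Feature) in bits.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .features import NUMERIC_FEATURES, REDUCED_FEATURES

CLASSES = ("E", "I", "EI")
BASES = "ACGT"


@dataclass
class NaiveBayesModel:
    """Class priors plus per-feature categorical tables / Gaussian params."""

    classes: tuple
    log_prior: dict  # class -> log prior
    cat_prob: dict  # feature -> class -> letter -> probability
    gauss: dict  # feature -> class -> (mean, var)
    alpha: float
    var_floor: float

    @property
    def cat_features(self) -> tuple:
        return tuple(self.cat_prob)

    @property
    def num_features(self) -> tuple:
        return tuple(self.gauss)

    @property
    def features(self) -> tuple:
        return self.cat_features + self.num_features

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "log_prior": self.log_prior,
            "cat_prob": self.cat_prob,
            "gauss": {f: {c: list(mv) for c, mv in d.items()} for f, d in self.gauss.items()},
            "alpha": self.alpha,
            "var_floor": self.var_floor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NaiveBayesModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            log_prior=d["log_prior"],
            cat_prob=d["cat_prob"],
            gauss={f: {c: tuple(mv) for c, mv in dd.items()} for f, dd in d["gauss"].items()},
            alpha=d["alpha"],
            var_floor=d["var_floor"],
        )


@dataclass(frozen=True)
class ClassPosterior:
    site_id: str
    p_E: float
    p_I: float
    p_EI: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_E, self.p_I, self.p_EI])


def fit_naive_bayes(
    X: pd.DataFrame,
    y: Sequence[str],
    alpha: float = 1.0,
    var_floor: float = 1e-9,
) -> NaiveBayesModel:
    """Fit priors, smoothed categorical tables and Gaussian parameters.

    Every class in :data:`CLASSES` must be represented in ``y``.
    """
    y = pd.Series(list(y), index=X.index)
    missing = [c for c in CLASSES if c not in set(y)]
    if missing:
        raise ValueError(f"training data lacks class(es): {', '.join(missing)}")
    n = len(y)
    log_prior = {c: math.log((y == c).sum() / n) for c in CLASSES}
    cat_features = [f for f in X.columns if f not in NUMERIC_FEATURES]
    num_features = [f for f in X.columns if f in NUMERIC_FEATURES]
    cat_prob: dict = {}
    for f in cat_features:
        cat_prob[f] = {}
        for c in CLASSES:
            col = X.loc[y == c, f]
            counts = col.value_counts()
            denom = len(col) + alpha * len(BASES)
            cat_prob[f][c] = {
                b: (counts.get(b, 0) + alpha) / denom for b in BASES
            }
    gauss: dict = {}
    for f in num_features:
        gauss[f] = {}
        for c in CLASSES:
            vals = X.loc[y == c, f].dropna().to_numpy(dtype=float)
            mean = float(vals.mean()) if len(vals) else 0.0
            var = float(vals.var()) if len(vals) else var_floor
            gauss[f][c] = (mean, max(var, var_floor))
    return NaiveBayesModel(
        classes=CLASSES, log_prior=log_prior, cat_prob=cat_prob, gauss=gauss,
        alpha=alpha, var_floor=var_floor,
    )


def predict_log_proba(model: NaiveBayesModel, X: pd.DataFrame) -> np.ndarray:
    """Log posteriors (n, 3) in class order E, I, EI.

    Missing values (NaN/None) and letters outside A/C/G/T drop that
    feature's likelihood term for that site.  Computation stays in log
    space throughout, so 31 features cannot under- or overflow.
    """
    n = len(X)
    lp = np.tile([model.log_prior[c] for c in model.classes], (n, 1)).astype(float)
    for f in model.cat_features:
        if f not in X.columns:
            continue
        col = X[f]
        for ci, c in enumerate(model.classes):
            probs = col.map(model.cat_prob[f][c])
            vals = probs.to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            lp[:, ci] += np.where(ok, np.log(np.where(ok, vals, 1.0)), 0.0)
    for f in model.num_features:
        if f not in X.columns:
            continue
        x = X[f].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        for ci, c in enumerate(model.classes):
            mean, var = model.gauss[f][c]
            term = -0.5 * (math.log(2 * math.pi * var) + (x - mean) ** 2 / var)
            lp[:, ci] += np.where(ok, np.where(ok, term, 0.0), 0.0)
    return lp - logsumexp(lp, axis=1, keepdims=True)


def predict_proba(model: NaiveBayesModel, X: pd.DataFrame) -> pd.DataFrame:
    proba = np.exp(predict_log_proba(model, X))
    return pd.DataFrame(proba, index=X.index, columns=[f"p_{c}" for c in model.classes])


def compute_posterior(model: NaiveBayesModel, vector: Mapping) -> ClassPosterior:
    """Posterior for a single feature mapping (Bayes rule in log space)."""
    site_id = str(vector.get("site_id", ""))
    row = {k: v for k, v in vector.items() if k != "site_id"}
    proba = np.exp(predict_log_proba(model, pd.DataFrame([row])))[0]
    return ClassPosterior(site_id=site_id, p_E=float(proba[0]), p_I=float(proba[1]),
                          p_EI=float(proba[2]))


def predict_class(posterior) -> str:
    """Maximum-posterior class; exact ties resolve in the order E > I > EI."""
    if isinstance(posterior, ClassPosterior):
        arr = posterior.as_array()
    else:
        arr = np.asarray(posterior, dtype=float)
    return CLASSES[int(np.argmax(arr))]


def compute_roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class RocResult:
    """Per-class one-vs-rest AUCs with ROC points from pooled CV posteriors."""

    auc: dict  # class -> AUC
    roc_points: dict  # class -> (fpr array, tpr array)
    scheme: str
    seed: int | None
    posteriors: pd.DataFrame = field(repr=False, default=None)
    labels: pd.Series = field(repr=False, default=None)


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    return fpr, tpr


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[str],
    folds: int = 10,
    loo: bool = False,
    seed: int = 0,
    alpha: float = 1.0,
    reduced: bool = False,
    var_floor: float = 1e-9,
) -> RocResult:
    """Seeded stratified k-fold (or leave-one-out) cross-validation.

    Out-of-fold posteriors are pooled before computing one-vs-rest AUC
    per class, so the reported AUCs describe a single pooled ROC.
    """
    y = pd.Series(list(y), index=X.index)
    if reduced:
        X = X[list(REDUCED_FEATURES)]
    if loo:
        splitter = LeaveOneOut()
        scheme = "leave-one-out"
    else:
        smallest = y.value_counts().min()
        if smallest < folds:
            raise ValueError(
                f"a class has only {smallest} members; use a smaller k than {folds}"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scheme = f"stratified {folds}-fold"
    oof = np.full((len(X), 3), np.nan)
    for train_idx, test_idx in splitter.split(X, y):
        model = fit_naive_bayes(X.iloc[train_idx], y.iloc[train_idx],
                                alpha=alpha, var_floor=var_floor)
        oof[test_idx] = np.exp(predict_log_proba(model, X.iloc[test_idx]))
    proba = pd.DataFrame(oof, index=X.index, columns=[f"p_{c}" for c in CLASSES])
    auc, points = {}, {}
    for ci, c in enumerate(CLASSES):
        binary = (y == c).to_numpy()
        auc[c] = compute_roc_auc(oof[:, ci], binary)
        points[c] = _roc_points(oof[:, ci], binary)
    return RocResult(auc=auc, roc_points=points, scheme=scheme,
                     seed=None if loo else seed, posteriors=proba, labels=y)


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class FeatureRanking:
    gains: pd.Series  # feature -> information gain, descending
    class_entropy: float
    numeric_bins: int


def rank_information_gain(
    X: pd.DataFrame, y: Sequence[str], numeric_bins: int = 10
) -> FeatureRanking:
    """Information gain per feature, numeric features quantile-binned.

    IG(f) = H(Class) - H(Class | f), in bits; 0 <= IG <= H(Class).
    """
    y = pd.Series(list(y), index=X.index)
    h_class = _entropy_bits(y.value_counts().to_numpy())
    gains = {}
    for f in X.columns:
        col = X[f]
        if f in NUMERIC_FEATURES or pd.api.types.is_numeric_dtype(col):
            if col.nunique(dropna=True) <= 1:
                gains[f] = 0.0
                continue
            # equal-frequency bins; tied values stay in one bin
            col = pd.qcut(col, min(numeric_bins, col.nunique()), duplicates="drop")
        cond = 0.0
        n = len(col)
        for _, grp in y.groupby(col, observed=True):
            cond += (len(grp) / n) * _entropy_bits(grp.value_counts().to_numpy())
        gains[f] = h_class - cond
    series = pd.Series(gains).sort_values(ascending=False)
    series.name = "information_gain"
    return FeatureRanking(gains=series, class_entropy=h_class, numeric_bins=numeric_bins)


def transfer_predict(
    model: NaiveBayesModel, X: pd.DataFrame, reduced: bool = False
) -> pd.DataFrame:
    """Posteriors for a new dataset under an already-fitted model.

    With ``reduced=True`` only the 5-feature view contributes likelihood
    terms, mirroring cross-species transfer where positional numbering
    far from the motif is not comparable.
    """
    wanted = list(REDUCED_FEATURES) if reduced else list(model.features)
    missing = [f for f in wanted if f not in X.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing: {', '.join(missing)}")
    return predict_proba(model, X[wanted])
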