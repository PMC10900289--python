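"""Random-forest modeling with threshold optimization.

One classifier is trained per feature space: hyperparameters are
chosen by a successive-halving random search with stratified 5-fold
cross-validation, the minority class randomly oversampled with
replacement *inside each training fold only* (validation folds are
never resampled).  Out-of-fold probabilities from per-fold refits of
the winning configuration drive the decision-threshold optimization
by Youden's J statistic (J = TPR − FPR, maximized over candidate
cuts), the model is refit on the full training data, and evaluation
reports balanced accuracy, sensitivity, specificity, F1, MCC,
AUC-ROC and AUCPR.  Ensembles soft-vote over per-model probabilities
rescaled so each model's threshold maps to 0.5.  The applicability
domain is characterized by binning test compounds on the Tanimoto
similarity of their nearest same-label training neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, tanimoto

__all__ = [
    "TrainedModel",
    "EvaluationReport",
    "ADReport",
    "cv_train",
    "youden_threshold",
    "evaluate",
    "ensemble_predict",
    "rescale_score",
    "ad_report",
    "predict_unlabeled",
]

log = logging.getLogger(__name__)

# Documented hyperparameter grid for the random forest.
PARAM_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 10, 20],
    "min_samples_split": [2, 5, 10],
    "max_features": ["sqrt", "log2"],
}


@dataclass
class TrainedModel:
    space_tag: str
    estimator: RandomForestClassifier
    threshold: float
    hyperparameters: dict
    training_keys: list[str]
    seed: int
    oof_scores: np.ndarray = field(repr=False, default=None)
    oof_labels: np.ndarray = field(repr=False, default=None)

    def predict_scores(self, fm: FeatureMatrix, keys=None) -> pd.Series:
        data = fm.data if keys is None else fm.data.loc[list(keys)]
        if list(data.columns) != list(self.feature_names_):
            raise ValueError(
                f"feature schema mismatch for space {self.space_tag!r}"
            )
        scores = self.estimator.predict_proba(data.to_numpy())[:, 1]
        return pd.Series(scores, index=data.index)

    @property
    def feature_names_(self):
        return self._feature_names

    @feature_names_.setter
    def feature_names_(self, names):
        self._feature_names = list(names)


@dataclass
class EvaluationReport:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    auc_roc: float
    auc_pr: float
    n_pos: int
    n_neg: int

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)


def _oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Random minority oversampling with replacement (training data only)."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    idx = []
    for cls, cnt in zip(classes, counts):
        cls_idx = np.flatnonzero(y == cls)
        idx.append(cls_idx)
        if cnt < n_max:
            idx.append(rng.choice(cls_idx, size=n_max - cnt, replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def _make_rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def _cv_auc(X, y, params, seed, n_folds, subsample_to=None):
    """Mean validation AUC-ROC across stratified folds; oversampling and
    any resource subsampling touch the training folds only."""
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, val_idx in skf.split(X, y):
        tr_idx = train_idx
        if subsample_to is not None and subsample_to < len(train_idx):
            # stratified subsample of the training fold (halving resource)
            keep = []
            for cls in np.unique(y[train_idx]):
                cls_idx = train_idx[y[train_idx] == cls]
                n_keep = max(2, int(round(subsample_to * len(cls_idx) / len(train_idx))))
                keep.append(rng.choice(cls_idx, size=min(n_keep, len(cls_idx)), replace=False))
            tr_idx = np.concatenate(keep)
        Xt, yt = _oversample(X[tr_idx], y[tr_idx], rng)
        clf = _make_rf(params, seed)
        clf.fit(Xt, yt)
        scores = clf.predict_proba(X[val_idx])[:, 1]
        if len(np.unique(y[val_idx])) == 2:
            aucs.append(roc_auc_score(y[val_idx], scores))
    return float(np.mean(aucs)) if aucs else 0.5


def _halving_search(X, y, seed, n_folds, n_candidates=8, ratio=3):
    """Successive-halving random search over :data:`PARAM_GRID`.

    Candidates are sampled without replacement from the grid; the
    resource is the training-subset size, starting at 1/ratio**r of
    the data and tripling each rung while the candidate set shrinks
    by the same factor.
    """
    rng = np.random.default_rng(seed)
    grid = [
        {"n_estimators": n, "max_depth": d, "min_samples_split": s, "max_features": f}
        for n in PARAM_GRID["n_estimators"]
        for d in PARAM_GRID["max_depth"]
        for s in PARAM_GRID["min_samples_split"]
        for f in PARAM_GRID["max_features"]
    ]
    order = rng.permutation(len(grid))
    candidates = [grid[i] for i in order[: min(n_candidates, len(grid))]]

    n = len(y)
    n_rungs = max(1, int(np.ceil(np.log(len(candidates)) / np.log(ratio))))
    for rung in range(n_rungs):
        resource = max(4 * n_folds, int(n / ratio ** (n_rungs - 1 - rung)))
        scored = [
            (_cv_auc(X, y, p, seed, n_folds, subsample_to=min(resource, n)), i, p)
            for i, p in enumerate(candidates)
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        n_keep = max(1, len(candidates) // ratio)
        candidates = [p for _, _, p in scored[:n_keep]]
        if len(candidates) == 1:
            break
    return candidates[0]


def cv_train(
    fm: FeatureMatrix,
    labels: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 5,
    space_tag: str | None = None,
    n_candidates: int = 8,
) -> TrainedModel:
    """Train a threshold-optimized random forest on one feature space.

    Hyperparameters come from the halving random search; the winning
    configuration is refit per fold to produce out-of-fold
    probabilities for every training compound, which feed the Youden-J
    threshold; the final estimator is refit on all (oversampled)
    training data.  Fully deterministic given ``seed``.
    """
    lab = labels.set_index("key") if "key" in labels.columns else labels
    keys = [k for k in fm.data.index if k in lab.index and pd.notna(lab.loc[k, "label"])]
    if len(keys) < 2 * n_folds:
        raise ValueError("fewer labeled compounds than 2×n_folds")
    X = fm.data.loc[keys].to_numpy(dtype=float)
    y = lab.loc[keys, "label"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < n_folds:
        raise ValueError("minority class smaller than the number of folds")

    best = _halving_search(X, y, seed, n_folds, n_candidates=n_candidates)

    # out-of-fold probabilities from per-fold refits of the best config
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for train_idx, val_idx in skf.split(X, y):
        Xt, yt = _oversample(X[train_idx], y[train_idx], rng)
        clf = _make_rf(best, seed)
        clf.fit(Xt, yt)
        oof[val_idx] = clf.predict_proba(X[val_idx])[:, 1]
    assert not np.isnan(oof).any()

    threshold = youden_threshold(oof, y)

    Xf, yf = _oversample(X, y, np.random.default_rng(seed))
    final = _make_rf(best, seed)
    final.fit(Xf, yf)

    model = TrainedModel(
        space_tag=space_tag or fm.space_tag,
        estimator=final,
        threshold=float(threshold),
        hyperparameters=dict(best),
        training_keys=list(keys),
        seed=seed,
        oof_scores=oof,
        oof_labels=y,
    )
    model.feature_names_ = fm.feature_names
    return model


def youden_threshold(oof_scores, labels) -> float:
    """Decision threshold maximizing Youden's J = TPR − FPR.

    Every distinct score is a candidate cut (predict positive when
    score >= cut); ties in J break toward the largest cut.
    """
    scores = np.asarray(oof_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to optimize the threshold")
    candidates = np.unique(scores)
    if len(candidates) == 1:
        log.warning("constant scores: threshold degenerate, J = 0 everywhere")
        return float(candidates[0])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    # J compared exactly over the common denominator n_pos*n_neg to keep
    # ties (and their resolution toward the largest cut) float-safe
    best_j, best_cut = None, candidates[0]
    for cut in candidates:
        pred = scores >= cut
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        j_scaled = tp * n_neg - fp * n_pos
        if best_j is None or j_scaled > best_j or (j_scaled == best_j and cut > best_cut):
            best_j, best_cut = j_scaled, cut
    return float(best_cut)


def evaluate(scores, labels, threshold: float) -> EvaluationReport:
    """Thresholded + threshold-free classification metrics."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    both = n_pos > 0 and n_neg > 0
    sens = recall_score(y, pred, pos_label=1, zero_division=0.0) if n_pos else float("nan")
    spec = recall_score(y, pred, pos_label=0, zero_division=0.0) if n_neg else float("nan")
    return EvaluationReport(
        balanced_accuracy=(sens + spec) / 2 if both else float("nan"),
        sensitivity=float(sens),
        specificity=float(spec),
        f1=float(f1_score(y, pred, zero_division=0.0)),
        mcc=float(matthews_corrcoef(y, pred)),
        auc_roc=float(roc_auc_score(y, scores)) if both else float("nan"),
        auc_pr=float(average_precision_score(y, scores)) if both else float("nan"),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def rescale_score(p: float, t: float) -> float:
    """Map probability ``p`` so the model's threshold ``t`` lands at 0.5.

    Piecewise-linear: s = 0.5·p/t for p <= t, else 0.5 + 0.5·(p−t)/(1−t).
    Degenerate thresholds (0 or 1) collapse to the respective constant.
    """
    if t <= 0.0:
        return 1.0 if p > 0 else 0.5
    if t >= 1.0:
        return 0.5 * p
    if p <= t:
        return 0.5 * p / t
    return 0.5 + 0.5 * (p - t) / (1.0 - t)


def ensemble_predict(
    models: list[TrainedModel],
    features_by_space: dict[str, FeatureMatrix],
    keys: list[str],
) -> pd.DataFrame:
    """Soft-voting ensemble over threshold-rescaled probabilities.

    Each model's probability is rescaled so its own threshold maps to
    0.5; the ensemble score is the mean of rescaled scores and the
    predicted label is 1 when the score >= 0.5.
    """
    if not models:
        raise ValueError("empty model list")
    per_model = []
    for m in models:
        if m.space_tag not in features_by_space:
            raise ValueError(f"missing feature space {m.space_tag!r}")
        fm = features_by_space[m.space_tag]
        missing = [k for k in keys if k not in fm.data.index]
        if missing:
            raise ValueError(
                f"missing keys in space {m.space_tag!r}: {missing[:3]}..."
            )
        p = m.predict_scores(fm, keys)
        per_model.append(p.map(lambda v, t=m.threshold: rescale_score(v, t)))
    score = pd.concat(per_model, axis=1).mean(axis=1)
    return pd.DataFrame(
        {"key": keys, "score": score.loc[keys].to_numpy(),
         "label": (score.loc[keys] >= 0.5).astype(int).to_numpy()}
    )


#: Applicability-domain similarity bins: half-open, last closed at 1.
AD_BINS = [(0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0)]


@dataclass
class ADReport:
    bins: list
    per_bin: dict  # bin -> {"n", "balanced_accuracy", "auc_pr"}


def ad_report(
    test_keys: list[str],
    model: TrainedModel,
    fingerprints: FeatureMatrix,
    labels: pd.DataFrame,
    features: FeatureMatrix | None = None,
) -> ADReport:
    """Model performance stratified by distance to the training set.

    For each test compound: the maximum Tanimoto similarity to any
    *same-label* training compound assigns it to one of five bins
    covering [0, 1]; per-bin balanced accuracy and AUCPR are computed
    from the model's thresholded scores (AUCPR is NA in single-class
    bins).
    """
    lab = labels.set_index("key") if "key" in labels.columns else labels
    train_fp = {}
    for cls in (0, 1):
        cls_keys = [
            k for k in model.training_keys if int(lab.loc[k, "label"]) == cls
        ]
        if not cls_keys:
            raise ValueError(f"no training compounds with label {cls}")
        train_fp[cls] = fingerprints.data.loc[cls_keys].to_numpy(dtype=bool)

    sims = []
    for k in test_keys:
        fp = fingerprints.data.loc[k].to_numpy(dtype=bool)
        pool = train_fp[int(lab.loc[k, "label"])]
        inter = np.logical_and(pool, fp).sum(axis=1)
        union = np.logical_or(pool, fp).sum(axis=1)
        with np.errstate(invalid="ignore"):
            s = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        sims.append(float(s.max()))
    sims = np.asarray(sims)

    space_fm = features if features is not None else fingerprints
    per_bin = {}
    y = lab.loc[test_keys, "label"].to_numpy(dtype=int)
    scores = None
    for lo, hi in AD_BINS:
        in_bin = (sims >= lo) & ((sims < hi) | (hi == 1.0))
        entry = {"n": int(in_bin.sum()), "balanced_accuracy": float("nan"),
                 "auc_pr": float("nan")}
        if in_bin.any():
            if scores is None:
                scores = model.predict_scores(space_fm, test_keys).to_numpy()
            yb, sb = y[in_bin], scores[in_bin]
            pred = (sb >= model.threshold).astype(int)
            if len(np.unique(yb)) == 2:
                entry["balanced_accuracy"] = float(balanced_accuracy_score(yb, pred))
                entry["auc_pr"] = float(average_precision_score(yb, sb))
            else:
                entry["balanced_accuracy"] = float(
                    recall_score(yb, pred, pos_label=int(yb[0]), zero_division=0.0)
                )
        per_bin[(lo, hi)] = entry
    return ADReport(bins=list(AD_BINS), per_bin=per_bin)


def predict_unlabeled(model: TrainedModel, fm: FeatureMatrix) -> pd.DataFrame:
    """Score and label compounds with no ground truth (e.g. ambiguous)."""
    if len(fm.data) == 0:
        return pd.DataFrame(columns=["key", "score", "label"])
    overlap = set(fm.data.index) & set(model.training_keys)
    if overlap:
        log.info("predict_unlabeled: %d keys overlap the training set", len(overlap))
    scores = model.predict_scores(fm)
    return pd.DataFrame(
        {"key": scores.index, "score": scores.to_numpy(),
         "label": (scores >= model.threshold).astype(int).to_numpy()}
    )
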