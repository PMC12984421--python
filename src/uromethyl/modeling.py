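"""Per-modality classifier training under repeated cross-validation.

Two gradient-boosted tree classifiers are trained — one on marker-window
AMF values (methylation model), one on genome-wide CNV log2 ratios — and
evaluated with 10-repeat stratified 3-fold cross-validation. Missing
feature values are imputed with the per-feature median of the *healthy
training* samples of the current fold, so no information flows from
validation or test samples into the learned state.

The xgboost-style hyperparameters (max_depth, eta, nrounds, subsample,
colsample_bytree, min_child_weight) are carried by `GBTConfig`; the learner
behind them is pluggable — any gradient-boosted binary classifier honoring
them qualifies. The default maps onto scikit-learn's
GradientBoostingClassifier (colsample_bytree -> max_features,
min_child_weight -> min_samples_leaf as the closest analogue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class CVScheme:
    """10-repeat stratified 3-fold CV: 30 fits per model."""

    n_folds: int = 3
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass(frozen=True)
class GBTConfig:
    max_depth: int = 3
    eta: float = 0.01
    nrounds: int = 200
    subsample: float = 0.7
    colsample: float = 0.6
    min_child_weight: int = 5


METHYL_GBT = GBTConfig(eta=0.01)
CNV_GBT = GBTConfig(eta=0.1)


def make_classifier(config: GBTConfig, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        max_depth=config.max_depth,
        learning_rate=config.eta,
        n_estimators=config.nrounds,
        subsample=config.subsample,
        max_features=config.colsample,
        min_samples_leaf=config.min_child_weight,
        random_state=seed,
    )


class HealthyMedianImputer:
    """Fill missing feature values with healthy-training medians.

    Medians are learned once from the healthy subset of the training matrix
    and reused for any later transform (validation/test folds), so there is
    no leakage. A feature missing in every healthy training sample falls
    back to 0.5 with a warning (features live on a [0,1]-like scale).
    """

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None

    def fit(self, train_matrix: np.ndarray, healthy_mask: np.ndarray) -> "HealthyMedianImputer":
        X = np.asarray(train_matrix, dtype=float)
        healthy_mask = np.asarray(healthy_mask, dtype=bool)
        if not healthy_mask.any():
            raise ValueError("no healthy samples in the training set")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X[healthy_mask], axis=0)
        n_empty = int(np.isnan(med).sum())
        if n_empty:
            warnings.warn(
                f"{n_empty} feature(s) missing in all healthy training samples; imputing 0.5"
            )
            med = np.where(np.isnan(med), 0.5, med)
        self.medians_ = med
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        X = np.array(matrix, dtype=float, copy=True)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = self.medians_[nan_c]
        return X

    def fit_transform(self, train_matrix, healthy_mask) -> np.ndarray:
        return self.fit(train_matrix, healthy_mask).transform(train_matrix)


def impute_with_healthy_median(
    train_matrix: np.ndarray, healthy_mask: np.ndarray
) -> tuple[np.ndarray, HealthyMedianImputer]:
    """Convenience wrapper: impute a training matrix, return it with the fitted imputer."""
    imp = HealthyMedianImputer()
    return imp.fit_transform(train_matrix, healthy_mask), imp


def make_folds(
    y: np.ndarray, scheme: CVScheme
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Fold index pairs per repeat: folds[r] = [(train_idx, val_idx) x n_folds].

    Stratified so every fold carries both classes; each sample is validated
    exactly once per repeat. Deterministic for a fixed scheme seed.
    """
    y = np.asarray(y)
    folds = []
    for r in range(scheme.n_repeats):
        splitter = StratifiedKFold(
            n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + r
        )
        folds.append([(tr, va) for tr, va in splitter.split(np.zeros(len(y)), y)])
    return folds


@dataclass
class CVResult:
    repeat_aucs: np.ndarray  # mean fold AUC per repeat
    oof_scores: np.ndarray  # n_repeats x n_samples out-of-fold probabilities
    folds: list = field(repr=False, default_factory=list)


def cv_model_scores(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    healthy_mask: np.ndarray,
    scheme: CVScheme = CVScheme(),
    config: GBTConfig = GBTConfig(),
    folds: list | None = None,
) -> CVResult:
    """Repeated-CV evaluation of one modality model.

    Per fold: healthy-median imputation learned on the training portion,
    a boosted-tree fit, out-of-fold probabilities on the validation
    portion. Per repeat the AUC is the mean of the fold AUCs. Deterministic
    under a fixed scheme seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    healthy_mask = np.asarray(healthy_mask, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for cross-validation")
    if folds is None:
        folds = make_folds(y, scheme)

    oof = np.full((len(folds), len(y)), np.nan)
    repeat_aucs = np.zeros(len(folds))
    for r, fold_list in enumerate(folds):
        fold_aucs = []
        for f, (tr, va) in enumerate(fold_list):
            imp = HealthyMedianImputer().fit(X[tr], healthy_mask[tr])
            clf = make_classifier(config, seed=(scheme.seed * 1000 + r * 10 + f) % (2**31))
            clf.fit(imp.transform(X[tr]), y[tr])
            prob = clf.predict_proba(imp.transform(X[va]))[:, 1]
            oof[r, va] = prob
            fold_aucs.append(roc_auc_score(y[va], prob))
        repeat_aucs[r] = float(np.mean(fold_aucs))
    return CVResult(repeat_aucs=repeat_aucs, oof_scores=oof, folds=folds)


class FinalModel:
    """Imputer + boosted-tree scorer retrained on train+validation, applied
    once to the held-out test set."""

    def __init__(self, config: GBTConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        self.imputer = HealthyMedianImputer()
        self.clf = make_classifier(config, seed)

    def fit(self, X: np.ndarray, y: np.ndarray, healthy_mask: np.ndarray) -> "FinalModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("empty training set")
        Xi = self.imputer.fit_transform(X, healthy_mask)
        self.clf.fit(Xi, y)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xi = self.imputer.transform(np.asarray(X, dtype=float))
        return self.clf.predict_proba(Xi)[:, 1]


def fit_final_models(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    healthy_mask: np.ndarray,
    config: GBTConfig,
    seed: int = 0,
) -> FinalModel:
    return FinalModel(config, seed=seed).fit(features, labels, healthy_mask)
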