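"""Equal-weight ensemble scoring, feature-subset search, and evaluation.

Four per-sample features live on a [0,1] scale: the methylation model
probability, the CNV model probability, the inverted global methylation
(1 - GM), and the estimated tumor fraction. The ensemble score of a
feature subset is the equal-weight sum sum(w * S) with w = 1/|subset| —
i.e. the mean of the selected features. All 15 non-empty subsets of the
four features are scored by repeated-CV AUC using the out-of-fold modality
scores (the weights are fixed, nothing is refit); the winner has the
highest median per-repeat AUC, ties going to the smaller, then
lexicographically earlier subset.

Evaluation utilities: rank-based ROC/AUC, an operating threshold at a
target specificity derived from healthy scores, comparison and
OR-combination with a binary mutation test, and Vickers-Elkin net-benefit
decision curves.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

FEATURE_NAMES = ("methyl_score", "cnv_score", "gm_score", "tumor_fraction")


def enumerate_subsets(features: Sequence[str] = FEATURE_NAMES) -> list[tuple[str, ...]]:
    """All non-empty feature subsets, ordered by size then lexicographically."""
    feats = sorted(features)
    out: list[tuple[str, ...]] = []
    for r in range(1, len(feats) + 1):
        out.extend(combinations(feats, r))
    return out


def ensemble_score(
    scores: Mapping[str, float] | pd.DataFrame, subset: Sequence[str]
) -> float | np.ndarray:
    """Equal-weight ensemble score: the mean of the selected features.

    Accepts one sample (mapping) or many (DataFrame with feature columns).
    Raises if a selected feature is absent or missing — impute first.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    if isinstance(scores, pd.DataFrame):
        missing = set(subset) - set(scores.columns)
        if missing:
            raise KeyError(f"missing features: {sorted(missing)}")
        block = scores.loc[:, list(subset)].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ValueError("missing feature values; impute before scoring")
        return block.mean(axis=1)
    vals = np.array([scores[f] for f in subset], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing feature values; impute before scoring")
    return float(vals.mean())


def subset_search(
    oof_scores: Mapping[str, np.ndarray],
    labels: np.ndarray,
    folds: list,
) -> pd.DataFrame:
    """Score every feature subset by repeated-CV AUC of its ensemble score.

    ``oof_scores[name]`` is an (n_repeats x n_samples) out-of-fold score
    matrix on a common fold layout; per repeat, the AUC is the mean over
    validation folds of the AUC of the subset mean. Returns one row per
    subset with the per-repeat AUC vector and its median.
    """
    y = np.asarray(labels, dtype=int)
    names = list(oof_scores)
    stacks = {n: np.asarray(m, dtype=float) for n, m in oof_scores.items()}
    rows = []
    for subset in enumerate_subsets(names):
        per_repeat = []
        for r, fold_list in enumerate(folds):
            fold_aucs = []
            for _, va in fold_list:
                s = np.mean([stacks[n][r, va] for n in subset], axis=0)
                fold_aucs.append(roc_auc_score(y[va], s))
            per_repeat.append(float(np.mean(fold_aucs)))
        rows.append(
            {
                "subset": subset,
                "n_features": len(subset),
                "repeat_aucs": per_repeat,
                "median_auc": float(np.median(per_repeat)),
            }
        )
    return pd.DataFrame(rows)


def select_best_subset(search_table: pd.DataFrame) -> tuple[str, ...]:
    """Winning subset: highest median per-repeat AUC; ties broken by smaller
    subset, then lexicographic order."""
    if len(search_table) == 0:
        raise ValueError("empty subset-search table")
    tbl = search_table.assign(
        _key=list(zip(-search_table["median_auc"], search_table["n_features"], search_table["subset"]))
    )
    return tuple(tbl.sort_values("_key").iloc[0]["subset"])


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """AUC (rank/Mann-Whitney formulation, ties counted half) plus ROC points."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to compute ROC")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def threshold_at_specificity(
    healthy_scores: Sequence[float], target_spec: float = 0.80
) -> float:
    """Smallest threshold whose specificity on the given healthy scores is
    at least ``target_spec``, with calls positive iff score >= threshold.

    With ties at the cut the achieved specificity can exceed but never fall
    below the target.
    """
    if not (0 < target_spec <= 1):
        raise ValueError("target specificity must lie in (0, 1]")
    h = np.sort(np.asarray(healthy_scores, dtype=float))
    if len(h) < 5:
        raise ValueError("need at least 5 healthy scores to set an operating point")
    k = int(np.ceil(target_spec * len(h)))
    for v in np.unique(h[max(k - 1, 0):]):
        if np.sum(h < v) >= k:
            return float(v)
    return float(np.nextafter(h[-1], np.inf))


def sens_spec(calls: np.ndarray, labels: np.ndarray) -> dict:
    calls = np.asarray(calls, dtype=bool)
    y = np.asarray(labels, dtype=int).astype(bool)
    tp = int(np.sum(calls & y))
    fn = int(np.sum(~calls & y))
    tn = int(np.sum(~calls & ~y))
    fp = int(np.sum(calls & ~y))
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def compare_with_mutation(
    ensemble_calls: Sequence[bool],
    mutation_status: Sequence[str],
    labels: Sequence[int],
) -> dict:
    """Sensitivity/specificity of the mutation test, the ensemble, and their
    OR-combination (positive when either test is positive).

    Samples with missing mutation status are excluded with a warning. The
    OR rule guarantees sensitivity >= each component and specificity <=
    each component; both are asserted on every call.
    """
    calls = np.asarray(ensemble_calls, dtype=bool)
    mut = np.asarray(mutation_status, dtype=object)
    y = np.asarray(labels, dtype=int)
    known = np.isin(mut, ["positive", "negative"])
    if not known.all():
        import warnings

        warnings.warn(f"excluding {int((~known).sum())} sample(s) with unknown mutation status")
        calls, mut, y = calls[known], mut[known], y[known]
    mut_calls = mut == "positive"
    combined = mut_calls | calls
    report = {
        "mutation": sens_spec(mut_calls, y),
        "ensemble": sens_spec(calls, y),
        "combined_or": sens_spec(combined, y),
        "n": int(len(y)),
    }
    comb, parts = report["combined_or"], (report["mutation"], report["ensemble"])
    assert all(comb["sensitivity"] >= p["sensitivity"] - 1e-12 for p in parts if p["sensitivity"] == p["sensitivity"])
    assert all(comb["specificity"] <= p["specificity"] + 1e-12 for p in parts if p["specificity"] == p["specificity"])
    return report


def net_benefit(tp: int, fp: int, n: int, pt: float) -> float:
    """Vickers-Elkin net benefit at threshold probability pt."""
    if not (0 <= pt < 1):
        raise ValueError("threshold probability must lie in [0, 1)")
    return tp / n - (fp / n) * pt / (1 - pt)


def decision_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    pt_grid: Sequence[float],
    or_calls: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Net-benefit curve of a [0,1]-scaled score (positive iff score >= pt),
    with treat-all and treat-none reference lines; ``or_calls`` optionally
    adds a combined strategy that also calls positive when a second binary
    test (e.g. mutation) is positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int).astype(bool)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in pt_grid:
        if not (0 <= pt < 1):
            raise ValueError("pt grid values must lie in [0, 1)")
        calls = s >= pt
        cs = sens_spec(calls, y)
        row = {
            "pt": float(pt),
            "model": net_benefit(cs["tp"], cs["fp"], n, pt),
            "treat_all": net_benefit(int(y.sum()), int((~y).sum()), n, pt),
            "treat_none": 0.0,
        }
        if or_calls is not None:
            cc = sens_spec(calls | np.asarray(or_calls, dtype=bool), y)
            row["model_or_mutation"] = net_benefit(cc["tp"], cc["fp"], n, pt)
        rows.append(row)
    assert prev >= 0  # labels sanity
    return pd.DataFrame(rows)
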