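"""Tissue-urine methylation concordance.

For a genomic region, the concordance of a matched tissue-urine pair is the
ratio of the urine AMF deviation to the tissue AMF deviation, both measured
from the healthy-urine baseline:

    concordance = (AMF_urine - AMF_healthy) / (AMF_tissue - AMF_healthy)

A positive ratio means urine moved in the same direction as tissue; under a
simple tumor/background mixture its expectation is the urine tumor fraction.
Per region, the median ratio across pairs is summarized, and the fraction
of regions with positive median is reported separately for marker and
background (non-marker) regions — marker regions are expected to be
strongly enriched for positive concordance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DENOM_TOL = 1e-6


def concordance_ratio(
    amf_urine: float, amf_tissue: float, healthy_mean: float, tol: float = DENOM_TOL
) -> float:
    """Single-region, single-pair concordance ratio; NaN when the tissue
    deviation is below ``tol`` (undefined, region excluded for that pair)."""
    denom = amf_tissue - healthy_mean
    if abs(denom) < tol:
        return float("nan")
    return (amf_urine - healthy_mean) / denom


def summarize_concordance(
    tissue_amf: pd.DataFrame,
    urine_amf: pd.DataFrame,
    healthy_amf: pd.DataFrame,
    marker_ids: Sequence | None = None,
    tol: float = DENOM_TOL,
) -> tuple[pd.DataFrame, dict]:
    """Region-level concordance over matched tissue-urine pairs.

    ``tissue_amf`` and ``urine_amf`` must be row-aligned (row i of each is
    the same donor); ``healthy_amf`` provides the per-window baseline as the
    mean over healthy samples. Returns the per-window table (n_pairs_defined,
    median_ratio, positive, is_marker) and a summary dict with
    ``fraction_positive_markers`` and ``fraction_positive_background``
    (windows with no defined ratio are NA and excluded from the fractions).
    """
    if tissue_amf.shape != urine_amf.shape:
        raise ValueError("tissue and urine matrices must be pair-aligned")
    if len(tissue_amf) < 1:
        raise ValueError("need at least one matched pair")

    t = tissue_amf.to_numpy(dtype=float)
    u = urine_amf.to_numpy(dtype=float)
    h = np.nanmean(healthy_amf.to_numpy(dtype=float), axis=0)

    denom = t - h
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (u - h) / denom
    ratio[np.abs(denom) < tol] = np.nan

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_ratio = np.nanmedian(ratio, axis=0)
    n_defined = np.sum(~np.isnan(ratio), axis=0)

    cols = tissue_amf.columns
    is_marker = (
        cols.isin(marker_ids) if marker_ids is not None else np.zeros(len(cols), bool)
    )
    positive = pd.array(median_ratio > 0, dtype="boolean")
    positive[n_defined == 0] = pd.NA
    table = pd.DataFrame(
        {
            "n_pairs_defined": n_defined,
            "median_ratio": median_ratio,
            "positive": positive,
            "is_marker": is_marker,
        },
        index=cols,
    )
    table.index.name = "window_id"

    defined = table["n_pairs_defined"] > 0
    marker_def = defined & table["is_marker"]
    backgr_def = defined & ~table["is_marker"]
    summary = {
        "fraction_positive_markers": (
            float(table.loc[marker_def, "positive"].mean()) if marker_def.any() else float("nan")
        ),
        "fraction_positive_background": (
            float(table.loc[backgr_def, "positive"].mean()) if backgr_def.any() else float("nan")
        ),
        "n_marker_windows": int(marker_def.sum()),
        "n_background_windows": int(backgr_def.sum()),
    }
    return table, summary


def matched_and_cross_correlations(
    tissue_profiles: pd.DataFrame, urine_profiles: pd.DataFrame, method: str = "spearman"
) -> tuple[np.ndarray, np.ndarray]:
    """Profile correlations for donor-matched vs cross-donor tissue-urine pairs.

    Rows of the two frames are donor-aligned (n donors). Returns
    ``(within, between)``: n within-donor correlations and n*(n-1)
    cross-donor correlations (every ordered tissue_i - urine_j pair with
    i != j). Used to show patient-specific signal: matched pairs correlate
    higher than unmatched ones.
    """
    t = np.asarray(tissue_profiles, dtype=float)
    u = np.asarray(urine_profiles, dtype=float)
    if t.shape[0] != u.shape[0]:
        raise ValueError("tissue and urine profiles must be donor-aligned")
    n = t.shape[0]

    def corr(x, y):
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            return float("nan")
        if method == "spearman":
            return float(stats.spearmanr(x[ok], y[ok]).statistic)
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    within = np.array([corr(t[i], u[i]) for i in range(n)])
    between = np.array(
        [corr(t[i], u[j]) for i in range(n) for j in range(n) if i != j]
    )
    return within, between
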