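"""Differentially methylated marker selection.

Marker windows are called by contrasting cancer tissue AMF against healthy
urine AMF, window by window: Welch's unequal-variance t-test, Benjamini-
Hochberg correction across all tested windows, then thresholds on FDR
(< 1e-5) and absolute AMF difference (> 0.25). Windows must be observed in
at least 12 healthy and 4 cancer samples to enter testing. Direction is
hyper where cancer mean exceeds healthy mean, hypo otherwise — bladder
tumors yield predominantly hypermethylated markers against a backdrop of
global hypomethylation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_MAX = 1e-5
DELTA_MIN = 0.25
MIN_HEALTHY_SUPPORT = 12
MIN_CANCER_SUPPORT = 4


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided t-test (unequal variances, Welch-Satterthwaite df).

    Returns ``(t, p)``. Each group needs >= 2 finite values. With zero
    variance in both groups and equal means, t is 0 and p is NaN
    (undefined); such windows are skipped upstream.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, float("nan")) if a.mean() == b.mean() else (float("inf"), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Welch t over two samples x windows matrices with NaNs."""
    na = np.sum(~np.isnan(a), axis=0)
    nb = np.sum(~np.isnan(b), axis=0)
    ma = np.nanmean(a, axis=0)
    mb = np.nanmean(b, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
    sa = va / na
    sb = vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def select_markers(
    amf_cancer_tissue: pd.DataFrame,
    amf_healthy_urine: pd.DataFrame,
    windows: pd.DataFrame | None = None,
    fdr_max: float = FDR_MAX,
    delta_min: float = DELTA_MIN,
    min_healthy: int = MIN_HEALTHY_SUPPORT,
    min_cancer: int = MIN_CANCER_SUPPORT,
) -> pd.DataFrame:
    """Call differentially methylated marker windows.

    Parameters
    ----------
    amf_cancer_tissue, amf_healthy_urine
        Samples x windows AMF matrices over the same window set (NaN =
        missing). The contrast deliberately crosses biofluids: cancer
        *tissue* versus healthy *urine*.
    windows
        Optional window coordinate table (indexed by window id) to attach
        chrom/start/end to the result.

    Returns
    -------
    DataFrame indexed by window id with columns ``mean_cancer_amf``,
    ``mean_healthy_amf``, ``delta_amf``, ``t``, ``p_value``, ``fdr``,
    ``direction``, ``n_cancer_support``, ``n_healthy_support`` for the
    selected markers only. BH correction spans all support-passing,
    testable windows; thresholds are strict (fdr < fdr_max,
    |delta| > delta_min).
    """
    if not amf_cancer_tissue.columns.equals(amf_healthy_urine.columns):
        raise ValueError("cohorts must share the same window set")

    ca = amf_cancer_tissue.to_numpy(dtype=float)
    he = amf_healthy_urine.to_numpy(dtype=float)
    n_c = np.sum(~np.isnan(ca), axis=0)
    n_h = np.sum(~np.isnan(he), axis=0)
    support = (n_h >= min_healthy) & (n_c >= min_cancer)

    t, p = _welch_vectorized(ca, he)
    testable = support & np.isfinite(p)  # zero-variance-in-both windows drop out
    if not testable.any():
        warnings.warn("no window passes support filters; empty marker set")
        cols = [
            "mean_cancer_amf", "mean_healthy_amf", "delta_amf", "t",
            "p_value", "fdr", "direction", "n_cancer_support", "n_healthy_support",
        ]
        return pd.DataFrame(columns=cols)

    fdr = np.full(p.shape, np.nan)
    fdr[testable] = bh_adjust(p[testable])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(ca, axis=0)
        mean_h = np.nanmean(he, axis=0)
    delta = mean_c - mean_h

    selected = testable & (fdr < fdr_max) & (np.abs(delta) > delta_min)
    idx = amf_cancer_tissue.columns[selected]
    out = pd.DataFrame(
        {
            "mean_cancer_amf": mean_c[selected],
            "mean_healthy_amf": mean_h[selected],
            "delta_amf": delta[selected],
            "t": t[selected],
            "p_value": p[selected],
            "fdr": fdr[selected],
            "direction": np.where(delta[selected] > 0, "hyper", "hypo"),
            "n_cancer_support": n_c[selected],
            "n_healthy_support": n_h[selected],
        },
        index=idx,
    )
    out.index.name = "window_id"
    if windows is not None:
        out = windows.loc[out.index].join(out)
    return out


def write_marker_bed(markers: pd.DataFrame, path) -> None:
    """Write markers as BED6+ (chrom, start, end, id, -log10 fdr, direction, delta)."""
    if not {"chrom", "start", "end"}.issubset(markers.columns):
        raise ValueError("markers need chrom/start/end columns; pass windows= to select_markers")
    with np.errstate(divide="ignore"):
        score = -np.log10(markers["fdr"].to_numpy())
    bed = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "start": markers["start"],
            "end": markers["end"],
            "name": markers.index,
            "score": score,
            "direction": markers["direction"],
            "delta_amf": markers["delta_amf"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_marker_bed(path) -> pd.DataFrame:
    """Read a marker BED6+ file back; index is the window id."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "direction", "delta_amf"],
    )
    bed = bed.set_index("name")
    bed.index.name = "window_id"
    return bed
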