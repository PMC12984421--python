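"""Windowed methylation features from per-CpG counts.

The genome is tiled into fixed-width windows (default 300 bp, BED-style
0-based half-open coordinates). Per-CpG methylated/unmethylated read counts
are pooled within each window into an average methylation fraction (AMF):

    AMF(w) = sum(meth reads in w) / sum(meth + unmeth reads in w)

Windows overlapping a blacklist interval by >= 1 bp are dropped up front;
windows with insufficient read support are missing (NaN) per sample.
Sample-level summaries derived here: global methylation (mean AMF over
covered windows), its inversion 1 - GM used as a cancer feature (tumors are
globally hypomethylated), and cosine similarity of a sample's AMF profile
to a tissue reference profile.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONVERSION_THRESHOLD = 0.97
MIN_WINDOW_READS = 30


class ConversionQC(NamedTuple):
    efficiency: float
    passed: bool


def tile_windows(
    chrom_lengths: Mapping[str, int],
    window_bp: int = 300,
    blacklist: Sequence[tuple[str, int, int]] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tile chromosomes into fixed windows, dropping blacklisted ones.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome -> length in bp (> 0).
    window_bp
        Window width; the last window of a chromosome may be truncated.
    blacklist
        Iterable of (chrom, start, end) half-open intervals, or a DataFrame
        with those first three columns. A window overlapping any interval
        by at least 1 bp is removed.

    Returns
    -------
    DataFrame with columns ``chrom``, ``start``, ``end``; the index is the
    ordinal window id within the retained tiling.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    windows = pd.concat(rows, ignore_index=True)

    if blacklist is not None:
        if isinstance(blacklist, pd.DataFrame):
            intervals = list(
                zip(blacklist.iloc[:, 0], blacklist.iloc[:, 1], blacklist.iloc[:, 2])
            )
        else:
            intervals = list(blacklist)
        keep = np.ones(len(windows), dtype=bool)
        for chrom, b_start, b_end in intervals:
            if b_start >= b_end:
                raise ValueError(f"malformed blacklist interval {chrom}:{b_start}-{b_end}")
            mask = (
                (windows["chrom"] == chrom)
                & (windows["start"] < b_end)
                & (windows["end"] > b_start)
            )
            keep &= ~mask.to_numpy()
        windows = windows[keep].reset_index(drop=True)

    windows.index.name = "window_id"
    return windows


def read_blacklist(path) -> pd.DataFrame:
    """Read a 3-column BED blacklist (extra columns ignored)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end"]
    return bed


def conversion_efficiency(chh_converted: int, chh_total: int) -> ConversionQC:
    """Cytosine conversion efficiency from CHH-context counts.

    CHH cytosines are essentially unmethylated, so the fraction converted
    C->T estimates the enzymatic conversion rate. Samples below 97% are
    excluded from analysis.

    Raises
    ------
    ValueError
        If ``chh_total`` is zero (unevaluable sample) or counts are invalid.
    """
    if chh_total < 0 or chh_converted < 0:
        raise ValueError("CHH counts must be non-negative")
    if chh_total == 0:
        raise ValueError("no CHH cytosines sequenced; conversion efficiency unevaluable")
    if chh_converted > chh_total:
        raise ValueError("converted count exceeds total count")
    eff = chh_converted / chh_total
    return ConversionQC(efficiency=eff, passed=eff >= CONVERSION_THRESHOLD)


def read_bedgraph_counts(path) -> pd.DataFrame:
    """Read a bedGraph-like per-CpG count TSV.

    Accepts the 5-column dialect (chrom, start, end, meth_count,
    unmeth_count) and the 6-column dialect with a percent column between
    the coordinates and the counts (the percent is ignored).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 5:
        df.columns = ["chrom", "start", "end", "meth_count", "unmeth_count"]
    elif df.shape[1] >= 6:
        df = df.iloc[:, [0, 1, 2, 4, 5]]
        df.columns = ["chrom", "start", "end", "meth_count", "unmeth_count"]
    else:
        raise ValueError(f"expected >=5 columns in {path}, got {df.shape[1]}")
    return df


def assign_windows(
    chrom: np.ndarray, pos: np.ndarray, windows: pd.DataFrame
) -> np.ndarray:
    """Map positions to retained window ids; -1 where no window contains the position."""
    out = np.full(len(pos), -1, dtype=np.int64)
    pos = np.asarray(pos)
    chrom = np.asarray(chrom)
    for c, sub in windows.groupby("chrom", sort=False):
        sel = chrom == c
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub.index.to_numpy()
        p = pos[sel]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
        res = np.where(ok, ids[np.clip(j, 0, len(ids) - 1)], -1)
        out[sel] = res
    return out


def compute_amf(
    counts: pd.DataFrame,
    windows: pd.DataFrame,
    min_reads: int = MIN_WINDOW_READS,
    coverage_rule: str = "window_total",
) -> np.ndarray:
    """Pool per-CpG counts into one AMF value per window for one sample.

    ``coverage_rule`` controls the read-support filter:

    - ``"window_total"`` (default): the window is missing when the total
      meth+unmeth reads pooled over its CpGs fall below ``min_reads``.
      Chosen because AMF itself is defined on pooled window counts.
    - ``"per_cpg"``: the window is missing when any covered CpG
      individually has fewer than ``min_reads`` reads.

    Windows with no CpG coverage are always missing. Returns a float array
    aligned with ``windows.index`` (NaN = missing).
    """
    n = len(windows)
    meth = np.zeros(n)
    tot = np.zeros(n)
    if len(counts):
        wid = assign_windows(
            counts["chrom"].to_numpy(), counts["start"].to_numpy(), windows
        )
        inside = wid >= 0
        wid = wid[inside]
        m = counts["meth_count"].to_numpy(dtype=float)[inside]
        u = counts["unmeth_count"].to_numpy(dtype=float)[inside]
        np.add.at(meth, wid, m)
        np.add.at(tot, wid, m + u)
        if coverage_rule == "per_cpg":
            min_depth = np.full(n, np.inf)
            np.minimum.at(min_depth, wid, m + u)
        elif coverage_rule != "window_total":
            raise ValueError(f"unknown coverage_rule {coverage_rule!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        amf = meth / tot
    if coverage_rule == "window_total":
        amf[tot < min_reads] = np.nan
    else:
        amf[(tot == 0) | (min_depth < min_reads)] = np.nan
    return amf


def build_amf_matrix(
    tables: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    min_reads: int = MIN_WINDOW_READS,
    coverage_rule: str = "window_total",
) -> pd.DataFrame:
    """Stack per-sample AMF rows into a samples x windows matrix."""
    rows = {
        sid: compute_amf(tbl, windows, min_reads=min_reads, coverage_rule=coverage_rule)
        for sid, tbl in tables.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=windows.index)


def global_methylation(row: np.ndarray | pd.Series) -> tuple[float, float]:
    """Mean AMF over covered windows and its inversion (the cancer feature).

    Returns ``(gm, 1 - gm)``. Raises on an all-missing row.
    """
    vals = np.asarray(row, dtype=float)
    if np.isnan(vals).all():
        raise ValueError("cannot compute global methylation: all windows missing")
    gm = float(np.nanmean(vals))
    return gm, 1.0 - gm


def tissue_reference_profile(tissue_rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Region-wise mean AMF over tissue samples; NaN where any tissue row is missing."""
    arr = np.asarray(tissue_rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    ref = arr.mean(axis=0)  # propagates NaN: reference defined only where all covered
    return ref


def cosine_to_tissue_reference(
    sample_row: np.ndarray | pd.Series,
    tissue_rows: pd.DataFrame | np.ndarray,
) -> float:
    """Cosine similarity between a sample's AMF profile and the tissue reference.

    Restricted to windows that are non-missing in the sample and in every
    tissue row; raw AMF values, no centering.
    """
    sample = np.asarray(sample_row, dtype=float)
    ref = tissue_reference_profile(tissue_rows)
    shared = ~np.isnan(sample) & ~np.isnan(ref)
    if shared.sum() < 2:
        raise ValueError("fewer than 2 mutually covered windows")
    a = sample[shared]
    b = ref[shared]
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm profile; cosine undefined")
    return float(a @ b / (na * nb))
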