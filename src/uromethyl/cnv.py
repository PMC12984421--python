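"""Copy-number profiles and a simplified tumor-fraction estimator.

Read counts in 1-Mbp bins are normalized to equal totals and compared to a
panel-of-normals baseline (per-bin median of the scaled normals):

    log2_ratio(b) = log2(scaled_sample(b) / baseline(b))

In a tumor/background mixture with tumor fraction ``tf`` and clonal integer
copy number ``c`` in a segment, the expected ratio is

    log2((1 - tf) + tf * c / 2)

The tumor-fraction estimator exploits exactly this identity: over a grid of
candidate tf values, each bin is assigned the integer state c in {0..4}
whose expected ratio is closest to the observed one, and the tf minimizing
the total squared residual plus a parsimony penalty on non-diploid bins is
returned. This is a deliberately simple, deterministic stand-in for the
HMM-based estimators used on real shallow WGS data (no segmentation, no
subclonality, no GC/mappability correction); its role here is to supply a
scalar tumor-fraction feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = (0, 1, 2, 3, 4)
DEFAULT_TF_GRID = np.round(np.arange(0.0, 0.751, 0.01), 4)
# Penalty per unit of copy-state deviation from diploid: larger than the
# typical squared residual of bin noise (sd ~0.05-0.1 in log2 units) so
# flat-noise profiles stay diploid at tf = 0, smaller than the squared
# amplitude of a real event at tf >~ 0.1. Scaling with |c - 2| (not a flat
# non-diploid flag) breaks the exact aliasing between state 3 at tf and
# state 4 at tf/2 (both give the same expected ratio).
DEFAULT_PENALTY = 0.02


@dataclass
class TumorFractionEstimate:
    tf: float
    states: np.ndarray
    residual: float
    grid_residuals: dict = field(repr=False, default_factory=dict)


def log2_ratio_profile(
    sample_bins: np.ndarray | pd.Series,
    pon_bins: np.ndarray | pd.DataFrame,
) -> np.ndarray:
    """Per-bin log2 ratio of a sample against a panel of normals.

    ``pon_bins`` is normals x bins. Sample and every normal are scaled to
    unit total; the baseline is the per-bin median of the scaled normals.
    Ratios are NaN where the baseline is zero. Invariant to rescaling all
    sample counts by a constant.
    """
    s = np.asarray(sample_bins, dtype=float)
    pon = np.asarray(pon_bins, dtype=float)
    if pon.ndim == 1:
        pon = pon[None, :]
    if pon.shape[1] != s.shape[0]:
        raise ValueError("sample and panel must share the bin grid")
    if s.sum() <= 0:
        raise ValueError("sample has no reads")
    s_scaled = s / s.sum()
    pon_scaled = pon / pon.sum(axis=1, keepdims=True)
    baseline = np.median(pon_scaled, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(s_scaled / baseline)
    ratio[~np.isfinite(ratio)] = np.nan  # zero baseline or zero sample count
    return ratio


def expected_log2_ratio(tf: float, c: int | np.ndarray) -> np.ndarray:
    """Mixture identity: expected log2 ratio of a clonal copy-number c at tumor fraction tf."""
    mix = (1.0 - tf) + tf * np.asarray(c, dtype=float) / 2.0
    with np.errstate(divide="ignore"):
        return np.log2(mix)


def estimate_tumor_fraction(
    log2_ratios: np.ndarray | pd.Series,
    tf_grid: np.ndarray = DEFAULT_TF_GRID,
    states: tuple[int, ...] = STATES,
    penalty: float = DEFAULT_PENALTY,
    center: bool = True,
) -> TumorFractionEstimate:
    """Grid fit of tumor fraction from a log2-ratio profile.

    Profiles from `log2_ratio_profile` are defined only up to the
    equal-total scaling constant (a genome with gains is deflated overall),
    so by default the profile is re-centered on its median first — valid
    while the majority of bins are copy-neutral.

    Two steps:

    1. Detection: for each candidate tf, each bin takes the state minimizing
       its penalized cost (squared deviation from the expected ratio plus
       ``penalty`` per unit |c - 2|); the tf minimizing the summed cost
       fixes the per-bin states. Ties prefer the smaller tf (tf near 0 is
       otherwise unidentifiable: the all-diploid model fits any profile
       equally well at every tf).
    2. Refinement: tf is re-estimated as the median over non-diploid bins
       of the per-bin inversion of the mixture identity,
       tf_i = (2^r_i - 1) / (c_i/2 - 1). The median makes the estimate
       robust to a few noise bins mis-called as events, and decouples it
       from the parsimony penalty (which otherwise biases tf upward).

    tf = 0 (no event bins) forces an all-diploid state vector.
    """
    r = np.asarray(log2_ratios, dtype=float)
    ok = np.isfinite(r)
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing bins to estimate tumor fraction")
    r = r[ok]
    if center:
        r = r - np.median(r)

    states_arr = np.asarray(states)
    diploid_pos = int(np.where(states_arr == 2)[0][0])
    best = None
    grid_residuals = {}
    state_dev = np.abs(states_arr - 2)
    for tf in np.sort(np.asarray(tf_grid, dtype=float)):
        mu = expected_log2_ratio(tf, states_arr)  # len(states)
        cost = (r[:, None] - mu[None, :]) ** 2 + penalty * state_dev[None, :]
        cost[:, ~np.isfinite(mu)] = np.inf  # e.g. c=0 at tf=1
        if tf == 0.0:
            assign = np.full(len(r), diploid_pos)
        else:
            assign = np.argmin(cost, axis=1)
        objective = float(cost[np.arange(len(r)), assign].sum())
        grid_residuals[float(tf)] = objective
        if best is None or objective < best[0] - 1e-12:
            best = (objective, float(tf), states_arr[assign])

    objective, tf_hat, fitted = best
    nondiploid = fitted != 2
    if tf_hat > 0.0 and nondiploid.any():
        # re-center on the called-diploid bins: the initial whole-profile
        # median is pulled toward the events when they cover many bins
        if (~nondiploid).any():
            r = r - np.median(r[~nondiploid])
        implied = (2.0 ** r[nondiploid] - 1.0) / (fitted[nondiploid] / 2.0 - 1.0)
        tf_max = float(np.max(tf_grid))
        tf_hat = float(np.clip(np.median(implied), 0.0, tf_max))
    else:
        tf_hat = 0.0
    full_states = np.full(len(ok), 2, dtype=int)
    full_states[ok] = fitted
    if tf_hat == 0.0:
        full_states[:] = 2
    return TumorFractionEstimate(
        tf=tf_hat, states=full_states, residual=objective, grid_residuals=grid_residuals
    )


def tile_cnv_bins(chrom_lengths: dict, bin_bp: int = 1_000_000) -> pd.DataFrame:
    """Tile chromosomes into CNV bins (same convention as methylation windows)."""
    from .methylome import tile_windows

    bins = tile_windows(chrom_lengths, window_bp=bin_bp)
    bins.index.name = "bin_id"
    return bins


def read_cnv_counts(path) -> pd.DataFrame:
    """Read a per-sample CNV bin TSV (chrom, bin_start, bin_end, read_count)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "read_count"]
    return df
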