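"""Synthetic urine-cfDNA cohort generator with known ground truth.

The generator emulates the structure of a urine/tissue EM-seq study of
bladder cancer at desk scale, so that every downstream stage (AMF
windowing, marker calling, concordance, CNV, modeling, ensemble) can be
tested against planted truth:

- A shared healthy per-window methylation baseline is drawn once per cohort
  from a Beta distribution (bimodal, mostly-methylated genome). Each sample
  additionally gets a small global background offset (between-subject
  global-methylation variability) and independent per-window noise
  (inter-individual dispersion of locus methylation, which in real
  methylomes far exceeds binomial read noise), so no window is a clean
  replicate across subjects.
- Tumor methylomes carry planted DMRs — predominantly hypermethylated
  windows (placed where the baseline leaves room for the full effect, i.e.
  CpG-island-like unmethylated regions) plus a small hypomethylated set —
  and a stage-dependent global hypomethylation of all other windows.
- A fluid sample is a tumor/background mixture at a per-sample tumor
  fraction tf: per CpG, methylated reads ~ Binomial(depth, p) with
  p = (1 - tf) * p_healthy + tf * p_tumor and depth ~ Poisson(mean_depth).
  Tissue is pure tumor (tf = 1); plasma is urine with tf scaled down.
- CNV bin read counts scale with (1 - tf) + tf * c / 2 for clonal copy
  number c, with log-normal noise, matching the mixture identity the CNV
  module inverts.
- Mutation status of cancer samples is Bernoulli(mutation_sensitivity);
  healthy samples are mutation-negative (the panel is treated as fully
  specific).

Everything is driven by one RNG seed: identical params + seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import tile_cnv_bins
from .methylome import tile_windows

DEFAULT_COHORT_SIZES = {
    ("marker", "tissue", "cancer"): 14,
    ("marker", "urine", "cancer"): 14,   # matched urine of the tissue donors
    ("marker", "urine", "healthy"): 14,
    ("train", "urine", "cancer"): 31,
    ("train", "urine", "healthy"): 41,
    ("test", "urine", "cancer"): 37,
    ("test", "urine", "healthy"): 20,
}


@dataclass
class SimParams:
    """Generator configuration. Defaults state the emulated study design:
    300-bp methylation windows, 1-Mbp CNV bins, a marker cohort of 14 cancer
    tissues vs 14 healthy urines, 31+41 training and 37+20 test urines, a
    strongly hyper-skewed DMR set, and a mutation panel sensitivity of 30/37."""

    n_chrom: int = 2
    chrom_length_bp: int = 10_000_000
    window_bp: int = 300
    cnv_bin_bp: int = 1_000_000
    n_cpg_per_window: int = 4
    mean_depth: float = 50.0
    n_dmr_hyper: int = 200
    n_dmr_hypo: int = 10
    dmr_effect: float = 0.3
    baseline_beta_params: tuple[float, float] = (0.6, 0.25)
    sample_noise_sd: float = 0.02
    window_noise_sd: float = 0.05
    tf_by_stage: dict = field(
        default_factory=lambda: {"NMIBC": (0.1, 0.4), "MIBC": (0.3, 0.6)}
    )
    global_hypo_by_stage: dict = field(
        default_factory=lambda: {"NMIBC": 0.02, "MIBC": 0.05}
    )
    mibc_fraction: float = 0.15
    high_grade_fraction: float = 0.75
    cnv_segments: list | None = None  # default derived from bin count
    cnv_noise_sd: float = 0.1
    cnv_mean_reads_per_bin: float = 2000.0
    mutation_sensitivity: float = 30 / 37
    plasma_tf_factor: float = 0.3
    n_blacklist_per_chrom: int = 2
    cohort_sizes: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom <= 0 or self.chrom_length_bp <= 0 or self.window_bp <= 0:
            raise ValueError("genome dimensions must be positive")
        if not (0 < self.dmr_effect <= 1):
            raise ValueError("dmr_effect must lie in (0, 1]")
        if not self.cohort_sizes:
            raise ValueError("cohort_sizes is empty")
        for stage, (lo, hi) in self.tf_by_stage.items():
            if not (0 <= lo <= hi < 1):
                raise ValueError(f"tumor-fraction bounds for {stage} must lie in [0, 1)")
        n_windows_ub = self.n_chrom * -(-self.chrom_length_bp // self.window_bp)
        if self.n_dmr_hyper + self.n_dmr_hypo > n_windows_ub:
            raise ValueError("requested DMR count exceeds the number of windows")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chrom)}


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    dmr_windows: dict  # window_id -> "hyper" | "hypo"
    per_sample_tf: dict  # sample_id -> tumor fraction
    cnv_segments_per_sample: dict  # sample_id -> [(start_bin, end_bin, copies), ...]
    mutation_status: dict  # sample_id -> "positive" | "negative"

    def to_json(self) -> str:
        return json.dumps(
            {
                "dmr_windows": {str(k): v for k, v in self.dmr_windows.items()},
                "per_sample_tf": {k: float(v) for k, v in self.per_sample_tf.items()},
                "cnv_segments_per_sample": {
                    k: [[int(a), int(b), int(c)] for a, b, c in v]
                    for k, v in self.cnv_segments_per_sample.items()
                },
                "mutation_status": dict(self.mutation_status),
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimCohort:
    """In-memory simulated cohort with fast-path accessors.

    Per-sample CpG counts are held as compact arrays (`meth`, `depth`)
    over a shared CpG map; `counts_table` materializes the bedGraph-style
    DataFrame for a sample on demand.
    """

    params: SimParams
    windows: pd.DataFrame
    cnv_bins: pd.DataFrame
    blacklist: list
    cpg_chrom: np.ndarray
    cpg_pos: np.ndarray
    cpg_window: np.ndarray
    baseline: np.ndarray
    sample_sheet: pd.DataFrame
    meth: dict
    depth: dict
    cnv_counts: pd.DataFrame  # samples x bins
    qc_counts: pd.DataFrame  # sample_id, chh_converted, chh_total
    truth: SimTruth

    @property
    def sample_ids(self) -> list:
        return list(self.sample_sheet["sample_id"])

    def counts_table(self, sample_id: str) -> pd.DataFrame:
        d = self.depth[sample_id]
        m = self.meth[sample_id]
        return pd.DataFrame(
            {
                "chrom": self.cpg_chrom,
                "start": self.cpg_pos,
                "end": self.cpg_pos + 1,
                "meth_count": m,
                "unmeth_count": d - m,
            }
        )

    def amf_matrix(
        self, sample_ids=None, min_reads: int = 30
    ) -> pd.DataFrame:
        """Samples x windows AMF matrix (pooled window counts, window-total
        coverage rule), computed directly from the shared CpG->window map."""
        if sample_ids is None:
            sample_ids = self.sample_ids
        n_win = len(self.windows)
        rows = {}
        for sid in sample_ids:
            d = self.depth[sid].astype(np.float64)
            m = self.meth[sid].astype(np.float64)
            tot = np.bincount(self.cpg_window, weights=d, minlength=n_win)
            met = np.bincount(self.cpg_window, weights=m, minlength=n_win)
            with np.errstate(invalid="ignore", divide="ignore"):
                amf = met / tot
            amf[tot < min_reads] = np.nan
            rows[sid] = amf
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.windows.index)

    def subset(self, split=None, role=None, condition=None) -> list:
        sheet = self.sample_sheet
        mask = np.ones(len(sheet), dtype=bool)
        if split is not None:
            mask &= (sheet["split"] == split).to_numpy()
        if role is not None:
            mask &= (sheet["role"] == role).to_numpy()
        if condition is not None:
            mask &= (sheet["condition"] == condition).to_numpy()
        return list(sheet.loc[mask, "sample_id"])

    def write(self, outdir) -> None:
        write_cohort(self, outdir)


def _rng(seed: int, *key) -> np.random.Generator:
    """Independent, deterministic stream keyed by purpose.

    Keying streams by (seed, purpose, identifiers) rather than drawing from
    one sequential stream keeps every sample's draws independent of which
    other samples exist in the cohort — resizing the test split cannot
    perturb training samples."""
    digest = hashlib.sha256(repr((seed,) + key).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def _derive_segments(n_bins: int) -> list:
    """Default clonal events: a 3-copy gain over the first 30% of bins and a
    1-copy loss over bins [50%, 60%)."""
    gain_end = max(1, int(np.ceil(0.3 * n_bins)))
    loss_start = int(0.5 * n_bins)
    loss_end = max(loss_start + 1, int(0.6 * n_bins))
    return [(0, gain_end, 3), (loss_start, min(loss_end, n_bins), 1)]


def _blacklist_intervals(params: SimParams, rng: np.random.Generator) -> list:
    """Window-aligned excluded intervals, a couple per chromosome."""
    out = []
    n_win_per_chrom = params.chrom_length_bp // params.window_bp
    for chrom in params.chrom_lengths:
        if params.n_blacklist_per_chrom <= 0 or n_win_per_chrom < 4:
            continue
        picks = rng.choice(
            n_win_per_chrom, size=params.n_blacklist_per_chrom, replace=False
        )
        for w in np.sort(picks):
            start = int(w) * params.window_bp
            out.append((chrom, start, start + params.window_bp))
    return out


def simulate_cohort(params: SimParams | None = None) -> SimCohort:
    """Generate a full synthetic cohort. Deterministic for fixed params+seed."""
    params = params or SimParams()
    params.validate()
    rng = _rng(params.seed, "genome")

    # --- genome: analysis tiling minus blacklist; CpG map shared by all samples
    blacklist = _blacklist_intervals(params, rng)
    windows = tile_windows(params.chrom_lengths, params.window_bp, blacklist or None)
    n_win = len(windows)
    widths = (windows["end"] - windows["start"]).to_numpy()
    k = params.n_cpg_per_window
    if np.any(widths < k):
        raise ValueError("windows narrower than the requested CpG count")
    # k strictly increasing offsets per window: sorted floors + arange shift
    u = np.sort(rng.random((n_win, k)), axis=1)
    offsets = np.floor(u * (widths[:, None] - k)).astype(np.int64) + np.arange(k)
    cpg_pos = (windows["start"].to_numpy()[:, None] + offsets).ravel()
    cpg_chrom = np.repeat(windows["chrom"].to_numpy(), k)
    cpg_window = np.repeat(windows.index.to_numpy(), k)

    # --- healthy population baseline per window
    a, b = params.baseline_beta_params
    baseline = rng.beta(a, b, size=n_win)

    # --- plant DMRs where the baseline leaves room for the full effect
    margin = 0.02
    hyper_ok = np.flatnonzero(baseline <= 1 - params.dmr_effect - margin)
    hypo_ok = np.flatnonzero(baseline >= params.dmr_effect + margin)
    if len(hyper_ok) < params.n_dmr_hyper or len(hypo_ok) < params.n_dmr_hypo:
        raise ValueError("not enough eligible windows to plant the requested DMRs")
    hyper_idx = rng.choice(hyper_ok, size=params.n_dmr_hyper, replace=False)
    remaining = np.setdiff1d(hypo_ok, hyper_idx)
    hypo_idx = rng.choice(remaining, size=params.n_dmr_hypo, replace=False)
    window_ids = windows.index.to_numpy()
    dmr_windows = {int(window_ids[i]): "hyper" for i in np.sort(hyper_idx)}
    dmr_windows.update({int(window_ids[i]): "hypo" for i in np.sort(hypo_idx)})
    is_hyper = np.zeros(n_win, dtype=bool)
    is_hyper[hyper_idx] = True
    is_hypo = np.zeros(n_win, dtype=bool)
    is_hypo[hypo_idx] = True

    # --- CNV grid and default clonal events
    cnv_bins = tile_cnv_bins(params.chrom_lengths, params.cnv_bin_bp)
    n_bins = len(cnv_bins)
    segments = (
        params.cnv_segments if params.cnv_segments is not None else _derive_segments(n_bins)
    )
    copy_by_bin = np.full(n_bins, 2, dtype=int)
    for s, e, c in segments:
        if c < 0:
            raise ValueError("copy numbers must be non-negative")
        copy_by_bin[int(s): int(e)] = int(c)

    # --- patients: tissue/urine/plasma of the same (split, condition) share a donor
    groups = list(params.cohort_sizes.items())
    patients: dict[tuple, list[dict]] = {}
    patient_counter = 0
    for (split, role, condition), n in groups:
        key = (split, condition)
        have = len(patients.get(key, []))
        for j in range(have, n):
            patient_counter += 1
            prng = _rng(params.seed, "patient", split, condition, j)
            if condition == "cancer":
                stage = "MIBC" if prng.random() < params.mibc_fraction else "NMIBC"
                lo, hi = params.tf_by_stage[stage]
                urine_tf = float(prng.uniform(lo, hi))
                mutation = "positive" if prng.random() < params.mutation_sensitivity else "negative"
                grade = "high" if prng.random() < params.high_grade_fraction else "low"
            else:
                stage, urine_tf, mutation, grade = "NA", 0.0, "negative", "NA"
            patients.setdefault(key, []).append(
                {
                    "patient_id": f"PT{patient_counter:04d}",
                    "stage": stage,
                    "urine_tf": urine_tf,
                    "mutation_status": mutation,
                    "grade": grade,
                }
            )

    # --- per-sample signal and reads
    sheet_rows = []
    meth: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    cnv_rows = {}
    per_sample_tf = {}
    seg_per_sample = {}
    mut_status = {}
    qc_rows = []
    gh_map = params.global_hypo_by_stage

    for (split, role, condition), n in groups:
        for i in range(n):
            pat = patients[(split, condition)][i]
            sid = f"{split}_{role}_{condition}_{i + 1:03d}"
            srng = _rng(params.seed, "sample", sid)
            if condition == "healthy":
                tf = 0.0
            elif role == "tissue":
                tf = 1.0
            elif role == "plasma":
                tf = pat["urine_tf"] * params.plasma_tf_factor
            else:
                tf = pat["urine_tf"]

            delta = srng.normal(0.0, params.sample_noise_sd)
            eps = srng.normal(0.0, params.window_noise_sd, size=n_win)
            p_healthy = np.clip(baseline + delta + eps, 0.0, 1.0)
            gh = gh_map.get(pat["stage"], 0.0) if condition == "cancer" else 0.0
            p_tumor = np.clip(p_healthy - gh, 0.0, 1.0)
            p_tumor[is_hyper] = np.minimum(1.0, p_healthy[is_hyper] + params.dmr_effect)
            p_tumor[is_hypo] = np.maximum(0.0, p_healthy[is_hypo] - params.dmr_effect)
            p_mix = (1.0 - tf) * p_healthy + tf * p_tumor

            d = srng.poisson(params.mean_depth, size=n_win * k).astype(np.int32)
            p_cpg = np.repeat(p_mix, k)
            m = srng.binomial(d, p_cpg).astype(np.int32)
            meth[sid] = m
            depth[sid] = d

            cbin = copy_by_bin if condition == "cancer" else np.full(n_bins, 2)
            mult = (1.0 - tf) + tf * cbin / 2.0
            noise = 2.0 ** srng.normal(0.0, params.cnv_noise_sd, size=n_bins)
            cnv_rows[sid] = np.rint(
                params.cnv_mean_reads_per_bin * mult * noise
            ).astype(np.int64)

            eff = srng.uniform(0.975, 0.995)
            chh_total = 100_000
            qc_rows.append(
                {
                    "sample_id": sid,
                    "chh_converted": int(round(eff * chh_total)),
                    "chh_total": chh_total,
                }
            )

            sheet_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pat["patient_id"],
                    "role": role,
                    "condition": condition,
                    "stage": pat["stage"],
                    "grade": pat["grade"],
                    "mutation_status": pat["mutation_status"] if condition == "cancer" else "negative",
                    "split": split,
                }
            )
            per_sample_tf[sid] = tf
            mut_status[sid] = sheet_rows[-1]["mutation_status"]
            if condition == "cancer":
                seg_per_sample[sid] = [(int(s), int(e), int(c)) for s, e, c in segments]

    sample_sheet = pd.DataFrame(sheet_rows)
    cnv_counts = pd.DataFrame.from_dict(
        cnv_rows, orient="index", columns=cnv_bins.index
    )
    truth = SimTruth(
        dmr_windows=dmr_windows,
        per_sample_tf=per_sample_tf,
        cnv_segments_per_sample=seg_per_sample,
        mutation_status=mut_status,
    )
    return SimCohort(
        params=params,
        windows=windows,
        cnv_bins=cnv_bins,
        blacklist=blacklist,
        cpg_chrom=cpg_chrom,
        cpg_pos=cpg_pos,
        cpg_window=cpg_window,
        baseline=baseline,
        sample_sheet=sample_sheet,
        meth=meth,
        depth=depth,
        cnv_counts=cnv_counts,
        qc_counts=pd.DataFrame(qc_rows),
        truth=truth,
    )


def write_cohort(cohort: SimCohort, outdir) -> None:
    """Write the cohort as plain-text artifacts: one bedGraph-like count TSV
    and one CNV bin TSV per sample, a sample sheet, CHH QC counts, the
    blacklist BED, and the truth JSON."""
    outdir = Path(outdir)
    (outdir / "counts").mkdir(parents=True, exist_ok=True)
    (outdir / "cnv").mkdir(parents=True, exist_ok=True)
    for sid in cohort.sample_ids:
        cohort.counts_table(sid).to_csv(
            outdir / "counts" / f"{sid}.bedgraph.tsv", sep="\t", header=False, index=False
        )
        bins = cohort.cnv_bins.copy()
        bins["read_count"] = cohort.cnv_counts.loc[sid].to_numpy()
        bins.to_csv(outdir / "cnv" / f"{sid}.cnv.tsv", sep="\t", header=False, index=False)
    cohort.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    cohort.qc_counts.to_csv(outdir / "chh_counts.tsv", sep="\t", index=False)
    with open(outdir / "blacklist.bed", "w") as fh:
        for chrom, s, e in cohort.blacklist:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    (outdir / "truth.json").write_text(cohort.truth.to_json())
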