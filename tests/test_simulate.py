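import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uromethyl.methylome import build_amf_matrix
from uromethyl.simulate import SimParams, simulate_cohort

from conftest import tiny_params


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        p1 = tiny_params(seed=5)
        p2 = tiny_params(seed=5)
        c1, c2 = simulate_cohort(p1), simulate_cohort(p2)
        sid = c1.sample_ids[0]
        assert c1.sample_sheet.equals(c2.sample_sheet)
        np.testing.assert_array_equal(c1.meth[sid], c2.meth[sid])
        np.testing.assert_array_equal(c1.cpg_pos, c2.cpg_pos)
        assert c1.cnv_counts.equals(c2.cnv_counts)
        assert c1.truth.to_json() == c2.truth.to_json()

    def test_different_seed_differs(self):
        c1 = simulate_cohort(tiny_params(seed=5))
        c2 = simulate_cohort(tiny_params(seed=6))
        sid = c1.sample_ids[0]
        assert not np.array_equal(c1.meth[sid], c2.meth[sid])


class TestSignalModel:
    def test_zero_tf_dmr_windows_match_baseline(self):
        """With tf = 0 everywhere, designated DMR windows show the healthy
        baseline within binomial sampling error."""
        sizes = {("train", "urine", "healthy"): 12}
        p = tiny_params(seed=7, cohort_sizes=sizes, sample_noise_sd=0.0, window_noise_sd=0.0, mean_depth=100)
        c = simulate_cohort(p)
        amf = c.amf_matrix()
        dmr_ids = list(c.truth.dmr_windows)
        pos = {w: i for i, w in enumerate(c.windows.index)}
        for w in dmr_ids[:20]:
            observed = amf[w].mean()
            expected = c.baseline[pos[w]]
            # 12 samples x ~400 reads: binomial SE < 0.008
            assert observed == pytest.approx(expected, abs=0.03)

    def test_pure_tumor_delta_amf_matches_effect(self):
        """At tf = 1 and deep coverage, hyper-DMR windows sit dmr_effect
        above the healthy mean (Monte-Carlo check of the configured shift)."""
        sizes = {
            ("marker", "tissue", "cancer"): 10,
            ("marker", "urine", "healthy"): 10,
        }
        p = tiny_params(
            seed=8, cohort_sizes=sizes, mean_depth=200, sample_noise_sd=0.0, window_noise_sd=0.0,
            global_hypo_by_stage={"NMIBC": 0.0, "MIBC": 0.0},
        )
        c = simulate_cohort(p)
        amf = c.amf_matrix()
        sheet = c.sample_sheet.set_index("sample_id")
        tumor = amf.loc[sheet.index[sheet["role"] == "tissue"]]
        healthy = amf.loc[sheet.index[sheet["condition"] == "healthy"]]
        hyper = [w for w, d in c.truth.dmr_windows.items() if d == "hyper"]
        delta = (tumor[hyper].mean() - healthy[hyper].mean()).mean()
        assert delta == pytest.approx(p.dmr_effect, abs=0.02)

    def test_healthy_tf_zero_in_truth(self, tiny_cohort):
        sheet = tiny_cohort.sample_sheet
        for sid in sheet.loc[sheet["condition"] == "healthy", "sample_id"]:
            assert tiny_cohort.truth.per_sample_tf[sid] == 0.0

    def test_global_hypomethylation_in_tumors(self):
        """Healthy genome-wide mean AMF exceeds MIBC tumors' mean when the
        stage hypomethylation shift is positive."""
        sizes = {
            ("marker", "tissue", "cancer"): 10,
            ("marker", "urine", "healthy"): 10,
        }
        p = tiny_params(
            seed=9, cohort_sizes=sizes, mibc_fraction=1.0, sample_noise_sd=0.005,
            global_hypo_by_stage={"NMIBC": 0.05, "MIBC": 0.05}, n_dmr_hyper=5, n_dmr_hypo=0,
        )
        c = simulate_cohort(p)
        amf = c.amf_matrix()
        sheet = c.sample_sheet.set_index("sample_id")
        gm_tumor = amf.loc[sheet.index[sheet["role"] == "tissue"]].mean(axis=1)
        gm_healthy = amf.loc[sheet.index[sheet["condition"] == "healthy"]].mean(axis=1)
        assert gm_healthy.mean() > gm_tumor.mean()

    def test_cnv_log2_expectation_matches_mixture_identity(self):
        """CNV bin counts in a gained segment reproduce
        log2((1-tf) + tf*c/2) against a healthy panel."""
        from uromethyl.cnv import expected_log2_ratio, log2_ratio_profile

        sizes = {
            ("train", "urine", "cancer"): 20,
            ("train", "urine", "healthy"): 20,
        }
        p = tiny_params(
            seed=10, cohort_sizes=sizes, cnv_noise_sd=0.01,
            tf_by_stage={"NMIBC": (0.4, 0.4), "MIBC": (0.4, 0.4)},
            cnv_segments=[(0, 3, 3)],
        )
        c = simulate_cohort(p)
        sheet = c.sample_sheet.set_index("sample_id")
        pon = c.cnv_counts.loc[sheet.index[sheet["condition"] == "healthy"]].to_numpy()
        cancers = sheet.index[sheet["condition"] == "cancer"]
        gained = []
        for s in cancers:
            prof = log2_ratio_profile(c.cnv_counts.loc[s].to_numpy(), pon)
            # profiles are defined up to the equal-total scaling constant;
            # re-center on the neutral bins before comparing amplitudes
            gained.append(prof[:3] - np.median(prof[3:]))
        expected = expected_log2_ratio(0.4, 3)
        assert np.mean(gained) == pytest.approx(expected, abs=0.02)

    def test_mutation_positive_rate_matches_sensitivity(self):
        """Empirical mutation-positive fraction among cancer patients stays
        inside a 99.9% binomial envelope of the configured sensitivity."""
        sizes = {("train", "urine", "cancer"): 300}
        p = tiny_params(seed=12, cohort_sizes=sizes, n_cpg_per_window=1, mean_depth=1)
        c = simulate_cohort(p)
        n_pos = sum(v == "positive" for v in c.truth.mutation_status.values())
        lo, hi = stats.binom.interval(0.999, 300, p.mutation_sensitivity)
        assert lo <= n_pos <= hi


class TestStructure:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimParams(cohort_sizes={}).validate()
        with pytest.raises(ValueError):
            tiny_params(n_dmr_hyper=10**6).validate()
        with pytest.raises(ValueError):
            tiny_params(dmr_effect=0.0).validate()
        with pytest.raises(ValueError):
            tiny_params(tf_by_stage={"NMIBC": (0.5, 1.0), "MIBC": (0.3, 0.6)}).validate()

    def test_cpg_positions_strictly_increasing(self, tiny_cohort):
        tbl = tiny_cohort.counts_table(tiny_cohort.sample_ids[0])
        for _, sub in tbl.groupby("chrom"):
            assert (np.diff(sub["start"]) > 0).all()

    def test_matched_tissue_urine_share_patient(self, tiny_cohort):
        sheet = tiny_cohort.sample_sheet
        tis = sheet.query("split == 'marker' and role == 'tissue'")
        uri = sheet.query("split == 'marker' and role == 'urine' and condition == 'cancer'")
        assert sorted(tis["patient_id"]) == sorted(uri["patient_id"])

    def test_fast_amf_path_matches_reference_route(self, tiny_cohort, tiny_amf):
        """The cohort's array fast path agrees with computing AMF from the
        written bedGraph-style table through the methylome module."""
        sid = tiny_cohort.sample_ids[3]
        via_counts = build_amf_matrix(
            {sid: tiny_cohort.counts_table(sid)}, tiny_cohort.windows
        )
        pd.testing.assert_frame_equal(
            via_counts, tiny_amf.loc[[sid]], check_exact=False, atol=1e-12
        )

    def test_written_cohort_roundtrip(self, tmp_path, tiny_cohort):
        from uromethyl.methylome import read_bedgraph_counts
        from uromethyl.simulate import write_cohort

        write_cohort(tiny_cohort, tmp_path)
        sid = tiny_cohort.sample_ids[0]
        back = read_bedgraph_counts(tmp_path / "counts" / f"{sid}.bedgraph.tsv")
        orig = tiny_cohort.counts_table(sid)
        np.testing.assert_array_equal(back["meth_count"], orig["meth_count"])
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "sample_sheet.tsv").exists()
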