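import dataclasses

import pytest

from uromethyl.simulate import SimParams, simulate_cohort

# Desk-scale genome used for cohort-level tests: 1 chromosome of 1 Mbp with
# 100-kbp CNV bins (>= 10 bins for the tumor-fraction fit), 3,334 windows.
TINY_COHORT_SIZES = {
    ("marker", "tissue", "cancer"): 14,
    ("marker", "urine", "cancer"): 14,
    ("marker", "urine", "healthy"): 14,
    ("train", "urine", "cancer"): 12,
    ("train", "urine", "healthy"): 14,
    ("test", "urine", "cancer"): 10,
    ("test", "urine", "healthy"): 8,
}


def tiny_params(seed: int = 11, **overrides) -> SimParams:
    base = dict(
        n_chrom=1,
        chrom_length_bp=1_000_000,
        cnv_bin_bp=100_000,
        n_dmr_hyper=40,
        n_dmr_hypo=4,
        cohort_sizes=dict(TINY_COHORT_SIZES),
        seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_params())


@pytest.fixture(scope="session")
def tiny_amf(tiny_cohort):
    return tiny_cohort.amf_matrix()
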