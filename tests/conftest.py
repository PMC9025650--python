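import numpy as np
import pandas as pd
import pytest

from epigx import dataio
from epigx.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one effect of every planted kind."""
    cfg = SimConfig(
        n_subjects=300,
        n_probes=60,
        n_snps=200,
        seed=42,
        planted_meqtl=[("snp_00010", 0.06)],
        planted_gxe=[("snp_00020", 0.06)],
        planted_gxmeth=[("snp_00030", 0.9)],
        planted_sem=[("cg_00007", 3, "high"), ("cg_00011", 2, "low")],
    )
    samples, meth, geno, truth = simulate_cohort(cfg)
    samples = dataio.apply_exclusions(samples)
    return cfg, samples, meth, geno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects at all (global null)."""
    cfg = SimConfig(
        n_subjects=300,
        n_probes=60,
        n_snps=200,
        seed=7,
        exposure_variance_fraction=0.0,
        age_variance_fraction=0.0,
    )
    samples, meth, geno, truth = simulate_cohort(cfg)
    return cfg, dataio.apply_exclusions(samples), meth, geno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_samples():
    """Hand-built six-subject phenotype table spanning the three classes."""
    df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(6)],
        "age": [40.0, 45, 50, 55, 60, 65],
        "sex": [1, 0, 1, 1, 0, 1],
        "bmi": [28.0, 30, 32, 34, 36, 38],
        "hba1c": [5.2, 5.7, 5.9, 6.4, 6.5, 8.0],
        "self_report_dx_diabetes": [False, True, False, False, False, True],
        "self_report_rx_diabetes": [False, False, False, True, False, True],
    })
    return dataio.SampleTable(df)
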