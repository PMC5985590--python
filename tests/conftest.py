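import numpy as np
import pandas as pd
import pytest

from aspenscan.core import GenotypeMatrix, SweepModel
from aspenscan.simulate import CohortConfig, simulate_study_cohort


def make_genotypes(dosages, chrom="chr1", start=1, spacing=1):
    d = np.asarray(dosages, dtype=np.int8)
    m = d.shape[1]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": start + spacing * np.arange(m),
        "ref": "A", "alt": "C", "aa": ".",
    })
    return GenotypeMatrix(dosages=d, sites=sites)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests."""
    return simulate_study_cohort(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A lighter cohort for pipeline-level tests."""
    cfg = CohortConfig(n_background_snps=1200)
    return cfg, simulate_study_cohort(cfg, seed=3)


@pytest.fixture(scope="session")
def dating_model():
    """Sweep model at the dating-analysis scale (25-kb region)."""
    return SweepModel(Ne=92_000, mu=3.75e-8, r=0.729e-8, L=25_000,
                     s=0.5, T_fix=0.1, n_hap=24, sweep_pos=12_500)


@pytest.fixture(scope="session")
def reference_table(dating_model):
    """Shared 2000-row ABC reference table (built once per session)."""
    from aspenscan.abc import ABCPriors, build_reference_table

    return build_reference_table(ABCPriors(n_sims=2000, seed=11),
                                 dating_model)
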