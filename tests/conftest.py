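import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import telogrs as tg

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def weights():
    """The bundled seven-SNP instrument set."""
    return tg.default_weights()


@pytest.fixture(scope="session")
def table1():
    """Published per-SNP telomere and melanoma effects."""
    return tg.load_melanoma_effects()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest three-stratum simulated study used across tests."""
    cfg = tg.SimulationConfig(n_cases=800, n_controls=900, n_strata=3, seed=12345)
    dosages, cohort, truth = tg.simulate_cohort(cfg)
    return cfg, dosages, cohort, truth


def make_dosage_matrix(values, rsids, coded, other, sample_prefix="S", mask=None, chrom=None, pos=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return tg.DosageMatrix(
        sample_ids=np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object),
        rsids=np.array(rsids, dtype=object),
        values=values,
        mask=np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, dtype=bool),
        coded_allele=np.array(coded, dtype=object),
        other_allele=np.array(other, dtype=object),
        chrom=None if chrom is None else np.array(chrom, dtype=object),
        pos=None if pos is None else np.array(pos, dtype=int),
    )
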