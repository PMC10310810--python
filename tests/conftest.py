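import numpy as np
import pandas as pd
import pytest

from genoscape.datatypes import GenotypeDataset
from genoscape.synth import CohortConfig, simulate_cohort


def make_dataset(dosages, phenotype=None, age=None, sex=None, chrom="1"):
    """Small hand-rolled dataset helper used across test modules."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variant_meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "G",
        },
        index=[f"v{j}" for j in range(m)],
    )
    subject_meta = pd.DataFrame(
        {
            "phenotype": phenotype if phenotype is not None else np.nan,
            "age": age if age is not None else 70.0,
            "sex": sex if sex is not None else 1.0,
        },
        index=[f"s{i}" for i in range(n)],
    )
    return GenotypeDataset(dosages, variant_meta, subject_meta)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort for fast integration tests."""
    return CohortConfig(
        n_cases=150, n_controls=150, n_variants=400,
        causal_per_subtype=6, missing_rate=0.01, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)
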