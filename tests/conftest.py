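import numpy as np
import pandas as pd
import pytest

from noninvrna.simulate import SimConfig, simulate_counts, simulate_genotypes


@pytest.fixture(scope="session")
def small_sim():
    """A small 19-donor single-tissue cohort reused across tests."""
    cfg = SimConfig(
        n_genes=300,
        n_donors=19,
        tissues=("hair",),
        collections_per_donor=1,
        seed=7,
        depth_mean=2e5,
        depth_cv=0.2,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_geno():
    return simulate_genotypes(19, np.full(300, 0.3), seed=7)


@pytest.fixture()
def toy_counts():
    """Hand-sized count matrix with annotation for QC/normalization toys."""
    counts = pd.DataFrame(
        {"s1": [5, 3, 7], "s2": [10, 0, 2]},
        index=["pc_gene", "lnc_gene", "other_gene"],
    )
    annot = pd.DataFrame(
        {
            "biotype": ["protein_coding", "lncRNA", "other"],
            "length": [1000, 2000, 500],
            "chrom": ["1", "1", "2"],
            "tss": [100, 5000, 100],
        },
        index=counts.index,
    )
    return counts, annot
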