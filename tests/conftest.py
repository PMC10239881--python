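import numpy as np
import pytest

from ploidypop import synthio
from ploidypop.containers import DosageMatrix, make_site_table


@pytest.fixture(scope="session")
def two_pool_dataset():
    """Two divergent diploid gene pools plus ten 50:50 hybrids."""
    cfg = synthio.SimConfig(
        n_clusters=2,
        cluster_ploidy=(2, 2),
        n_per_cluster=(100, 100),
        n_loci=500,
        divergence_F=0.3,
        admixture_spec=((10, (0.5, 0.5)),),
        inheritance_mode=(None, None),
        seed=42,
    )
    truth, dosages, reads = synthio.simulate_dataset(cfg)
    return cfg, truth, dosages, reads


@pytest.fixture(scope="session")
def four_pool_dataset():
    """Study-like structure: 2 diploid + 2 tetraploid pools, 50:50 hybrids."""
    cfg = synthio.SimConfig(
        n_per_cluster=(50, 50, 50, 50),
        n_loci=300,
        admixture_spec=((5, (0.5, 0.5, 0.0, 0.0)), (5, (0.0, 0.0, 0.5, 0.5))),
        seed=7,
    )
    truth, dosages, reads = synthio.simulate_dataset(cfg)
    return cfg, truth, dosages, reads


def make_dosage_matrix(dosage, ploidy, missing=None, qual=1000.0, positions=None):
    """Hand-rolled DosageMatrix for fixture tests."""
    dosage = np.asarray(dosage, dtype=np.int64)
    n, l = dosage.shape
    if missing is None:
        missing = np.zeros((n, l), dtype=bool)
    sites = make_site_table(l, qual=qual)
    if positions is not None:
        sites["pos"] = np.asarray(positions, dtype=np.int64)
    return DosageMatrix(
        dosage=dosage,
        missing=np.asarray(missing, dtype=bool),
        ploidy=np.asarray(ploidy, dtype=np.int64),
        samples=[f"s{i}" for i in range(n)],
        sites=sites,
    )
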