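import numpy as np
import pandas as pd
import pytest

from popsaturate.synthetic_population import SimConfig, write_outputs
from popsaturate.variant_io_filter import GenotypeMatrix


def make_matrix(dosage, ploidy=None, chrom="chrI", start_pos=100, spacing=50):
    """GenotypeMatrix from a plain dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, L = dosage.shape
    if ploidy is None:
        ploidy = np.full(n, 2, dtype=np.int16)
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * L,
            "pos": start_pos + spacing * np.arange(L),
            "ref": ["A"] * L,
            "alt": ["T"] * L,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=loci,
        dosage=dosage,
        ploidy=np.asarray(ploidy, dtype=np.int16),
    )


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small clade-structured population: 4 clades x 6 + 4 admixed, 280-kb genome."""
    return SimConfig(
        seed=1,
        n_loci=600,
        samples_per_clade=6,
        n_admixed=4,
        chrom_lengths={
            "chrI": 120_000,
            "chrII": 80_000,
            "chrIII": 50_000,
            "chrIV": 30_000,
        },
    )


@pytest.fixture(scope="session")
def tiny_sim_dir(tiny_sim_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    paths = write_outputs(tiny_sim_config, str(out))
    return paths
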