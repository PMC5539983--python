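import numpy as np
import pandas as pd
import pytest

import seqherit as sh


@pytest.fixture(scope="session")
def ld_genotypes():
    """Moderate-LD copy-sampled genotypes, QC-filtered (session-shared)."""
    g = sh.simulate_genotypes(
        sh.SimulationConfig(
            n_individuals=120,
            n_variants=400,
            n_chromosomes=2,
            chromosome_length_bp=50_000_000,
            founder_pool_size=40,
            seed=11,
        )
    )
    g, _ = sh.qc_filter(g)
    return g


@pytest.fixture
def make_genotypes():
    """Factory for hand-built dosage matrices."""

    def _make(dosages, pos=None, chrom=None, ids=None):
        dosages = np.asarray(dosages, dtype=float)
        n, m = dosages.shape
        pos = list(range(1, m + 1)) if pos is None else pos
        chrom = ["chr1"] * m if chrom is None else chrom
        ids = [f"i{k}" for k in range(n)] if ids is None else ids
        variants = pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(m)],
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "C",
            }
        )
        return sh.GenotypeMatrix(ids, variants, dosages)

    return _make
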