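import numpy as np
import pandas as pd
import pytest

from polypat.core import CallMatrix
from polypat.simulate import MatingDesign, SIModel, simulate_founders


def make_call_matrix(genotypes, depths=None, chrom="Chr01"):
    """Build a CallMatrix from a plain genotype array for tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "T",
        },
        index=pd.Index([f"{chrom}_{j:04d}" for j in range(m)], name="marker"),
    )
    if depths is not None:
        depths = np.asarray(depths, dtype=np.int32)
    return CallMatrix(
        individuals=[f"I{i:03d}" for i in range(n)],
        markers=markers,
        genotypes=g,
        allele_depths=depths,
    )


@pytest.fixture
def si_model():
    return SIModel(k_s=3, k_z=3, s_locus=("Chr01", 40.0),
                   z_locus=("Chr02", 60.0))


@pytest.fixture
def small_founders(si_model):
    return simulate_founders(
        n_parents=12,
        n_chromosomes=3,
        markers_per_chromosome=40,
        maf_range=(0.1, 0.5),
        si_model=si_model,
        seed=42,
    )


@pytest.fixture
def equal_design():
    return MatingDesign(fecundity=np.ones(12), progeny_per_mother=20)
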