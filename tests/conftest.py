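import numpy as np
import pandas as pd
import pytest

from invfinder.datatypes import GenotypeMatrix


def make_gm(calls, cm=None, lg=None, contigs=None, distances=None, source="transect"):
    """Assemble a GenotypeMatrix from a plain array with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    loci = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(s)],
            "contig": contigs if contigs is not None else [f"c{j}" for j in range(s)],
            "contig_pos": [10 + 40 * j for j in range(s)],
            "linkage_group": lg if lg is not None else 1,
            "cm_position": cm if cm is not None else np.arange(s, dtype=float),
        }
    )
    individuals = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n)],
            "source": source,
            "transect_distance": distances if distances is not None else np.linspace(0, 152, n),
            "family_id": pd.NA,
            "parent_role": pd.NA,
        }
    )
    return GenotypeMatrix(calls, loci, individuals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gm(rng):
    calls = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
    return make_gm(calls)
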