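import numpy as np
import pandas as pd
import pytest

from allelemine.paralogs import ParalogSignature
from allelemine.simulate import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def signature() -> ParalogSignature:
    """Four-paralog signature with a built-in ambiguous pair.

    The fusion row is the positionwise union of the two single-gene rows,
    so {fusion + reference copy} and {copy A + copy B} predict identical
    observables — the classic ambiguous-haplotype situation.
    """
    return ParalogSignature(
        gene_id="HvCBF2",
        positions=[63, 260, 632, 770, 841, 920],
        alleles={
            "morex_CBF2a": "ACGTAG",
            "nure_CBF2a": "ATGCAG",
            "nure_CBF2b": "GCGTTG",
            "CBF2ab_fusion": "GTGCTG",
        },
        ref_paralog="morex_CBF2a",
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=60,
        category_counts={"cultivar": 30, "landrace": 20, "wild": 8, "unknown": 2},
        snp_sites=20,
        n_frost_genotypes=20,
        n_replicates=4,
    )


@pytest.fixture(scope="session")
def small_panel(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    truth, inputs = simulate_panel(small_config, seed=7, out_dir=out)
    return {"truth": truth, "inputs": inputs, "dir": out}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
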