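import numpy as np
import pandas as pd
import pytest

from panelforge.variants import GenotypeMatrix


def make_geno(calls, chroms=None, positions=None, samples=None, **info):
    """Small GenotypeMatrix builder for hand-crafted call matrices."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    loci = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * n_l,
            "pos": positions if positions is not None else np.arange(1, n_l + 1) * 100,
            "ref": ["A"] * n_l,
            "alt": ["G"] * n_l,
        }
    )
    for k, v in info.items():
        loci[k] = v
    return GenotypeMatrix(
        samples or [f"s{i}" for i in range(n_s)], loci, calls
    )


@pytest.fixture
def toy_geno():
    """4 samples x 5 loci with one missing call and one monomorphic locus."""
    return make_geno(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 0, 0, 2],
            [2, -1, 1, 0, 0],
            [0, 0, 1, 0, 1],
        ]
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """One shared Balding-Nichols simulation (F=0.1, 2x50, 20k loci)."""
    from panelforge import simdata

    cfg = simdata.PopulationSimConfig(
        n_loci=20_000, samples_per_pop=(50, 50), target_fst=0.1, seed=11
    )
    return simdata.simulate_populations(cfg)
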