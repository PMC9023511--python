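import numpy as np
import pandas as pd
import pytest

from retropop.genotypes import GenotypeMatrix, LOCUS_COLUMNS
from retropop.simulate import SimulationConfig, simulate_study, simulate_two_pops


@pytest.fixture(scope="session")
def default_study():
    """One seeded default synthetic study, shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def two_pop_strong():
    """Two clearly diverged populations (F=0.2) for separation tests."""
    conf = SimulationConfig(n_loci=500, divergence_F=0.2, seed=7)
    rng = np.random.default_rng(7)
    return simulate_two_pops(30, 30, conf, rng)


def make_matrix(dosage, chrom=None, pos=None, qual=None, depth=None, samples=None,
                ref=None, alt=None):
    """Small-matrix builder for hand-constructed fixtures."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else [f"sc{j}" for j in range(L)],
            "pos": pos if pos is not None else np.arange(1, L + 1) * 10_000,
            "ref": ref if ref is not None else ["A"] * L,
            "alt": alt if alt is not None else ["G"] * L,
            "qual": qual if qual is not None else [100.0] * L,
            "mean_depth": [30.0] * L,
        },
        columns=LOCUS_COLUMNS,
    )
    geno = GenotypeMatrix(
        dosage=dosage,
        samples=samples or [f"S{i}" for i in range(n)],
        loci=loci,
        depth=np.asarray(depth, dtype=np.int32) if depth is not None else None,
    )
    if depth is not None:
        geno.loci["mean_depth"] = geno.mean_site_depth()
    return geno
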