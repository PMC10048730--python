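import numpy as np
import pytest

from landgen import GenotypeTable, RasterSurface, TransformSpec
from landgen.synthetic import (SyntheticTruth, make_landscape,
                               sample_locations)

# canonical seed for every stochastic fixture in the suite
SEED = 7


@pytest.fixture(scope="session")
def seed():
    return SEED


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def smooth_raster():
    return make_landscape("smooth", (24, 24), seed=SEED)


@pytest.fixture(scope="session")
def dem_raster():
    return make_landscape("dem", (24, 24), seed=SEED)


@pytest.fixture(scope="session")
def recovery_truth():
    """High-signal self-consistency regime used by the recovery suites."""
    return SyntheticTruth(TransformSpec("Monomolecular", 3.0, 100.0),
                          sigma2_u=0.01, sigma2_e=0.02, seed=SEED)


@pytest.fixture
def toy_genotypes():
    """AA, BB, AB at one locus; the hand-enumerable Rousset toy."""
    alleles = np.array([[[1, 1]], [[2, 2]], [[1, 2]]])
    return GenotypeTable(["A", "B", "C"], alleles, ["L1"])


def random_genotypes(rng, n=10, n_loci=6, n_alleles=4, missing_frac=0.0):
    alleles = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2))
    if missing_frac:
        mask = rng.random((n, n_loci)) < missing_frac
        mask[:, 0] = False  # keep one locus complete so every row is typed
        alleles[mask] = -1
    ids = [f"i{k:02d}" for k in range(n)]
    return GenotypeTable(ids, alleles, [f"L{j}" for j in range(n_loci)])
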