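import numpy as np
import pytest

from metgblup.relmat import GenotypeMatrix, Pedigree
from metgblup.simulate import cs_config, simulate


@pytest.fixture(scope="session")
def fullsib_pedigree():
    """Two unrelated founders, two full sibs, one inbred offspring of the sibs."""
    return Pedigree(
        [
            ("P1", "0", "0"),
            ("P2", "0", "0"),
            ("O1", "P1", "P2"),
            ("O2", "P1", "P2"),
            ("O3", "O1", "O2"),
        ]
    )


@pytest.fixture(scope="session")
def hw_genotypes():
    """50 x 200 founder panel in Hardy-Weinberg proportions."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.1, 0.9, size=200)
    codes = rng.binomial(2, p, size=(50, 200))
    keep = (codes.mean(axis=0) > 0) & (codes.mean(axis=0) < 2)
    return GenotypeMatrix([f"I{i}" for i in range(50)], codes[:, keep])


@pytest.fixture(scope="session")
def small_bundle():
    """Small but informative simulated trial reused across tests."""
    return simulate(
        cs_config(seed=11, n_families=24, progeny_per_family=6, n_snps=400)
    )
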