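import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seabream.io import GenotypeTable

settings.register_profile(
    "seabream",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seabream")


@pytest.fixture
def diagnostic_baselines() -> GenotypeTable:
    """Two populations fixed for disjoint alleles at one locus.

    Population A is fixed for allele 1, population B for allele 2, each with
    500 fish, so baseline frequency smoothing is negligible and the mixture
    problem reduces to counting carriers of the diagnostic allele.
    """
    n = 500
    geno = np.concatenate(
        [np.full((n, 1, 2), 1, dtype=int), np.full((n, 1, 2), 2, dtype=int)]
    )
    ids = [f"A_{i}" for i in range(n)] + [f"B_{i}" for i in range(n)]
    pops = ["A"] * n + ["B"] * n
    return GenotypeTable(ids, pops, ["L1"], geno)


def make_diagnostic_mixture(n_a: int, n_b: int) -> GenotypeTable:
    """Mixture carrying the diagnostic allele of source A in n_a fish."""
    geno = np.concatenate(
        [np.full((n_a, 1, 2), 1, dtype=int), np.full((n_b, 1, 2), 2, dtype=int)]
    )
    ids = [f"m{i}" for i in range(n_a + n_b)]
    return GenotypeTable(ids, ["mix"] * (n_a + n_b), ["L1"], geno)
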