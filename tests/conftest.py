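"""Shared fixtures: small deterministic genotype matrices and cohorts."""

import numpy as np
import pytest

from coralmme.data import GenotypeMatrix


def make_matrix(dosages, sample_ids=None, chrom=None, pos=None, locus_ids=None):
    """GenotypeMatrix from a plain dosage array with generated coordinates."""
    d = np.asarray(dosages, dtype=np.int8)
    n, L = d.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if chrom is None:
        chrom = ["1"] * L
    if pos is None:
        pos = np.arange(1, L + 1) * 1000
    if locus_ids is None:
        locus_ids = [f"{c}:{p}" for c, p in zip(chrom, pos)]
    return GenotypeMatrix(
        d, np.array(sample_ids, dtype=object), np.array(locus_ids, dtype=object),
        np.array(chrom, dtype=object), np.array(pos),
        np.array(["A"] * L, dtype=object), np.array(["T"] * L, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """10 samples x 200 loci, segregating, complete calls."""
    p = rng.uniform(0.1, 0.9, size=200)
    d = rng.binomial(2, p, size=(10, 200))
    return make_matrix(d)


@pytest.fixture(scope="session")
def small_cohort():
    """Full synthetic cohort (pre + post + juveniles) at desk scale."""
    from coralmme.simulate import CohortConfig, simulate_full_cohort

    cfg = CohortConfig(rng_seed=7, n_loci=800, n_causal=60,
                       heritability_h2=0.5)
    return simulate_full_cohort(cfg)
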