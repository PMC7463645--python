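"""Shared fixtures: small random genotype matrices and replicate fixtures."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from histstr.types import AllelePair, GenotypeMatrix, ReplicateRecord, ReplicateTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(entries, populations, loci) -> GenotypeMatrix:
    return GenotypeMatrix(entries, populations, loci)


@pytest.fixture
def random_matrix_factory():
    """Factory for small random two-or-more-population matrices (seeded)."""

    def build(
        seed: int,
        n_pops: int = 2,
        n_per_pop: int = 6,
        n_loci: int = 2,
        n_alleles: int = 4,
        p_missing: float = 0.0,
    ) -> GenotypeMatrix:
        rng = np.random.default_rng(seed)
        loci = [f"L{k}" for k in range(n_loci)]
        alleles = [100 + 2 * i for i in range(n_alleles)]
        entries = {}
        populations = {}
        for p in range(n_pops):
            pop = f"P{p}"
            freqs = rng.dirichlet(np.ones(n_alleles))
            for i in range(n_per_pop):
                sample = f"{pop}_{i}"
                populations[sample] = pop
                for locus in loci:
                    if p_missing and rng.random() < p_missing:
                        entries[(sample, locus)] = None
                        continue
                    a, b = rng.choice(alleles, size=2, p=freqs)
                    entries[(sample, locus)] = AllelePair(int(a), int(b))
        return GenotypeMatrix(entries, populations, loci)

    return build


def records_for(sample, locus, genotypes, pop="POP", start=1):
    """Replicate records from a list of (a, b) tuples or None for failures."""
    out = []
    for k, g in enumerate(genotypes):
        pair = None if g is None else AllelePair(*g)
        out.append(ReplicateRecord(sample, pop, locus, start + k, pair))
    return out


@pytest.fixture
def replicate_fixture():
    return records_for
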