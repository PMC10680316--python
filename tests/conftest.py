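from __future__ import annotations

import numpy as np
import pytest

from forensnp.loci import GenotypeMatrix, Locus
from forensnp.qc import compute_allele_frequencies
from forensnp.simulate import (SyntheticConfig, generate_population_genotypes,
                               sample_balding_nichols_freqs)


def make_matrix(genotype_strings, alleles_per_locus=None, chroms=None):
    """Build a GenotypeMatrix from rows like ["A/A A/C", "C/C ./."]."""
    rows = [s.split() for s in genotype_strings]
    n_loci = len(rows[0])
    alleles_per_locus = alleles_per_locus or [("A", "C")] * n_loci
    chroms = chroms or ["1"] * n_loci
    loci = [Locus(f"L{j}", chroms[j], j + 1, tuple(alleles_per_locus[j]))
            for j in range(n_loci)]
    calls = np.full((len(rows), n_loci, 2), -1, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == "./.":
                continue
            a, b = cell.split("/")
            calls[i, j] = sorted((loci[j].alleles.index(a), loci[j].alleles.index(b)))
    return GenotypeMatrix([f"S{i}" for i in range(len(rows))], loci, calls)


@pytest.fixture(scope="session")
def korean_like_panel():
    """A 400-locus single-population panel with sampled allele frequencies,
    shaped like a forensic SNP panel (~2% tri-allelic, MAF-rich)."""
    cfg = SyntheticConfig(n_loci=400, populations=("KOR",), F=0.0, seed=2024,
                          ancestral_maf_range=(0.1, 0.5))
    ft = sample_balding_nichols_freqs(cfg)
    gm, pops = generate_population_genotypes(ft, 157, seed=2025)
    return compute_allele_frequencies(gm, pops)


@pytest.fixture(scope="session")
def two_pop_genotypes():
    """Two Balding-Nichols populations at F = 0.1, modest size, with the
    sample -> population map (used by F_ST / PCA / I_n tests)."""
    cfg = SyntheticConfig(n_loci=800, populations=("P1", "P2"), F=0.1, seed=7)
    ft = sample_balding_nichols_freqs(cfg)
    gm, pops = generate_population_genotypes(ft, 50, seed=8)
    return gm, pops
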