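"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
enumeration, exact fractions, direct tallies) and never calls the package
code paths it is used to check.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# kinship: exhaustive pedigree enumeration
# ---------------------------------------------------------------------------

def unordered_genotypes(n_alleles: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]


def hwe_prob(g: tuple[int, int], f) -> float:
    i, j = g
    return f[i] * f[j] * (2.0 if i != j else 1.0)


def _m(a: int, x: int, n_alleles: int, mu: float) -> float:
    return 1.0 - mu if a == x else mu / (n_alleles - 1)


def gamete_prob(parent: tuple[int, int], x: int, f, mu: float) -> float:
    """P(transmitted allele = x | parent genotype), with mutation."""
    A = len(f)
    return 0.5 * (_m(parent[0], x, A, mu) + _m(parent[1], x, A, mu))


def child_prob(g: tuple[int, int], pa, pb, f, mu: float) -> float:
    """P(child genotype = g | both parent genotypes), unordered."""
    i, j = g
    p = gamete_prob(pa, i, f, mu) * gamete_prob(pb, j, f, mu)
    if i != j:
        p += gamete_prob(pa, j, f, mu) * gamete_prob(pb, i, f, mu)
    return p


def child_prob_random_mate(g: tuple[int, int], parent, f, mu: float) -> float:
    """P(child genotype | one known parent, mate drawn from HWE)."""
    return sum(hwe_prob(m, f) * child_prob(g, parent, m, f, mu)
               for m in unordered_genotypes(len(f)))


def pedigree_joint_prob(g1, g2, f, mu: float, relationship: str) -> float:
    """P(g1, g2) under explicit pedigree enumeration."""
    G = unordered_genotypes(len(f))
    rel = relationship.upper()
    if rel == "PC":
        return hwe_prob(g1, f) * child_prob_random_mate(g2, g1, f, mu)
    if rel == "FS":
        return sum(hwe_prob(pa, f) * hwe_prob(pb, f)
                   * child_prob(g1, pa, pb, f, mu) * child_prob(g2, pa, pb, f, mu)
                   for pa in G for pb in G)
    if rel == "HS":
        return sum(hwe_prob(s, f)
                   * child_prob_random_mate(g1, s, f, mu)
                   * child_prob_random_mate(g2, s, f, mu)
                   for s in G)
    if rel == "GG":
        total = 0.0
        for parent in G:
            p_par = sum(hwe_prob(m1, f) * child_prob(parent, g1, m1, f, mu) for m1 in G)
            total += p_par * child_prob_random_mate(g2, parent, f, mu)
        return hwe_prob(g1, f) * total
    if rel == "UNRELATED":
        return hwe_prob(g1, f) * hwe_prob(g2, f)
    raise ValueError(relationship)


def pedigree_lr(g1, g2, f, mu: float, relationship: str) -> float:
    """LR = P(g1, g2 | relationship) / [P(g1) P(g2)]."""
    return (pedigree_joint_prob(g1, g2, f, mu, relationship)
            / (hwe_prob(g1, f) * hwe_prob(g2, f)))


# ---------------------------------------------------------------------------
# HWE: exact-fraction enumeration for diallelic tables
# ---------------------------------------------------------------------------

def hwe_pvalue_enumeration(n_het: int, n_hom1: int, n_hom2: int) -> Fraction:
    """Exact conditional HWE p-value by direct enumeration with Fractions."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het

    def table_prob(h: int) -> Fraction:
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        return Fraction(
            math.factorial(n) * math.factorial(n_a) * math.factorial(n_b) * 2 ** h,
            math.factorial(ha) * math.factorial(hb) * math.factorial(h)
            * math.factorial(2 * n),
        )

    obs = table_prob(n_het)
    total = Fraction(0)
    for h in range(min(n_a, n_b) + 1):
        if (n_a - h) % 2 or (n_b - h) % 2:
            continue
        p = table_prob(h)
        if p <= obs:
            total += p
    return total


# ---------------------------------------------------------------------------
# misc direct tallies
# ---------------------------------------------------------------------------

def tally_allele_freqs(column, n_alleles: int) -> np.ndarray:
    """Pure-python allele frequency recount, ignoring (-1, -1) calls."""
    counts = [0] * n_alleles
    total = 0
    for a, b in column:
        if a == -1:
            continue
        counts[a] += 1
        counts[b] += 1
        total += 2
    return np.array(counts) / total


def classic_delete_one_jackknife(theta_hat: float, theta_j: np.ndarray) -> float:
    """SE of the classic equal-block delete-one jackknife."""
    g = len(theta_j)
    return math.sqrt((g - 1) / g * np.sum((theta_j - theta_j.mean()) ** 2))


def haplotype_count_r2(hap1: np.ndarray, hap2: np.ndarray) -> float:
    """r^2 by direct haplotype counting on phased 0/1 haplotype vectors."""
    pa = hap1.mean()
    pb = hap2.mean()
    pab = (hap1 * hap2).mean()
    D = pab - pa * pb
    return D * D / (pa * (1 - pa) * pb * (1 - pb))
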