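"""Pairwise kinship likelihood ratios under IBD-coefficient models.

A named relationship is a vector of IBD-sharing probabilities
``k = (k0, k1, k2)`` — the chance a relative pair shares 0, 1 or 2 alleles
identical by descent at an autosomal locus:

=============  ==================
relationship   (k0, k1, k2)
=============  ==================
parent-child   (0, 1, 0)
full sibling   (1/4, 1/2, 1/4)
half sibling   (1/2, 1/2, 0)
grandparent    (1/2, 1/2, 0)
unrelated      (1, 0, 0)
=============  ==================

The single-locus likelihood ratio for hypothesis H1 (the relationship)
against H2 (unrelated) is

    LR = [k0 P(g2) + k1 P1(g2 | g1) + k2 P2(g2 | g1)] / P(g2)

with P the Hardy–Weinberg genotype probability, P1 the probability of g2
given exactly one IBD allele (a uniformly chosen allele of g1 is transmitted
subject to mutation, the other allele drawn from the population), and
P2 = 1 iff g2 equals g1 as an unordered pair. Mutation redistributes a
transmitted allele to each of the other A-1 alleles with probability
mu/(A-1), so an apparent exclusion under PC yields a small positive LR
rather than zero. For non-inbred pairwise relationships this IBD model is
exact. Panel LRs multiply over loci (justified by the panel's LD screen)
and are accumulated in log10.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .loci import MISSING, FrequencyTable

DEFAULT_MU = 1.29e-8

RELATIONSHIP_K: dict[str, tuple[float, float, float]] = {
    "PC": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "GG": (0.5, 0.5, 0.0),
    "UNRELATED": (1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class KinshipModel:
    """A relationship hypothesis: IBD coefficients plus a per-meiosis,
    per-locus mutation rate."""

    name: str
    k: tuple[float, float, float]
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if abs(sum(self.k) - 1.0) > 1e-12 or any(not 0 <= v <= 1 for v in self.k):
            raise ValidationError(f"IBD coefficients must be in [0,1] and sum to 1: {self.k}")
        if self.mu < 0:
            raise ValidationError(f"mutation rate must be >= 0, got {self.mu}")

    @classmethod
    def from_name(cls, name: str, mu: float = DEFAULT_MU) -> "KinshipModel":
        key = name.upper()
        if key not in RELATIONSHIP_K:
            raise ValidationError(
                f"unknown relationship {name!r}; choose from {sorted(RELATIONSHIP_K)}")
        return cls(key, RELATIONSHIP_K[key], mu)


UNRELATED = KinshipModel("UNRELATED", RELATIONSHIP_K["UNRELATED"], 0.0)


# ---------------------------------------------------------------------------
# vectorized likelihood core: genotypes are (..., 2) allele-index arrays,
# freqs is (L, 3) zero-padded, n_alleles is (L,)
# ---------------------------------------------------------------------------

def _take_freq(freqs: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    full = np.broadcast_to(freqs, alleles.shape[:-1] + freqs.shape[-1:])
    return np.take_along_axis(full, alleles, axis=-1)


def _hwe_prob(g: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    pa = _take_freq(freqs, g)
    het = g[..., 0] != g[..., 1]
    return pa[..., 0] * pa[..., 1] * np.where(het, 2.0, 1.0)


def _mut(x: np.ndarray, y: np.ndarray, n_alleles: np.ndarray, mu: float) -> np.ndarray:
    """Transmission probability allele x -> allele y under the mutation model."""
    return np.where(x == y, 1.0 - mu, mu / (n_alleles - 1.0))


def _p1(g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray,
        n_alleles: np.ndarray, mu: float) -> np.ndarray:
    """P(g2 | g1, exactly one allele IBD)."""
    a, b = g1[..., 0], g1[..., 1]
    c, d = g2[..., 0], g2[..., 1]
    pc = _take_freq(freqs, g2)[..., 0]
    pd_ = _take_freq(freqs, g2)[..., 1]
    t_c = 0.5 * (_mut(a, c, n_alleles, mu) + _mut(b, c, n_alleles, mu))
    t_d = 0.5 * (_mut(a, d, n_alleles, mu) + _mut(b, d, n_alleles, mu))
    both = t_c * pd_ + t_d * pc
    return np.where(c == d, 0.5 * both, both)


def _lr_core(g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray,
             n_alleles: np.ndarray, model: KinshipModel) -> np.ndarray:
    k0, k1, k2 = model.k
    pg2 = _hwe_prob(g2, freqs)
    if np.any(pg2 <= 0):
        raise ValidationError("genotype with zero Hardy-Weinberg probability")
    same = (((g1[..., 0] == g2[..., 0]) & (g1[..., 1] == g2[..., 1]))
            | ((g1[..., 0] == g2[..., 1]) & (g1[..., 1] == g2[..., 0])))
    lr = np.full(pg2.shape, k0, dtype=float)
    if k1:
        lr = lr + k1 * _p1(g1, g2, freqs, n_alleles, model.mu) / pg2
    if k2:
        lr = lr + k2 * same / pg2
    return lr


def _check_alleles(g: np.ndarray, freqs: np.ndarray) -> None:
    if np.any(_take_freq(freqs, g) <= 0):
        raise ValidationError("genotype uses an allele with zero frequency")


def single_locus_lr(g1: Sequence[int], g2: Sequence[int], freqs: Sequence[float],
                    model: KinshipModel) -> float:
    """Single-locus LR for one genotype pair; genotypes are unordered
    allele-index pairs, ``freqs`` the locus's allele-frequency vector."""
    if not 2 <= len(freqs) <= 3:
        raise ValidationError("freqs must have 2 or 3 entries (one per declared allele)")
    f = np.zeros(3)
    f[: len(freqs)] = freqs
    na = np.array(float(len(freqs)))
    a1 = np.array(g1, dtype=np.int64)
    a2 = np.array(g2, dtype=np.int64)
    _check_alleles(a1, f)
    _check_alleles(a2, f)
    return float(_lr_core(a1, a2, f, na, model))


def _pop_freqs(ft: FrequencyTable, population: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(freqs (L,3), n_alleles (L,), available (L,)) for one population."""
    p = ft.pop_index(population)
    freqs = ft.freqs[p]
    n_alleles = np.array([loc.n_alleles for loc in ft.loci], dtype=float)
    return freqs, n_alleles, ft.available()[p]


def panel_log10_lr(g1: np.ndarray, g2: np.ndarray, ft: FrequencyTable,
                   model: KinshipModel, population: str | None = None
                   ) -> tuple[float, int]:
    """Sum of per-locus log10 LRs over the loci usable in both genotype
    vectors and the table; returns (log10 LR, number of skipped loci)."""
    population = population or ft.populations[0]
    freqs, n_alleles, avail = _pop_freqs(ft, population)
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    usable = avail & (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    n_skipped = int((~usable).sum())
    if not usable.any():
        raise UndefinedStatisticError("no usable loci shared by both genotype vectors")
    u = np.flatnonzero(usable)
    _check_alleles(g1[u], freqs[u])
    _check_alleles(g2[u], freqs[u])
    lrs = _lr_core(g1[u], g2[u], freqs[u], n_alleles[u], model)
    return float(np.sum(np.log10(lrs))), n_skipped


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _draw_alleles(freqs: np.ndarray, shape: tuple[int, ...],
                  rng: np.random.Generator) -> np.ndarray:
    """Categorical draws per locus; freqs (L, 3), shape broadcasting (..., L)."""
    cdf = np.cumsum(freqs, axis=-1)
    u = rng.random(shape)
    return (u[..., None] >= cdf).sum(axis=-1).astype(np.int64)


def _mutate(alleles: np.ndarray, n_alleles: np.ndarray, mu: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the equal-redistribution mutation model to transmitted alleles."""
    if mu == 0:
        return alleles
    hit = rng.random(alleles.shape) < mu
    shift = 1 + np.floor(rng.random(alleles.shape) * (n_alleles - 1)).astype(np.int64)
    return np.where(hit, (alleles + shift) % n_alleles.astype(np.int64), alleles)


def _simulate_pairs(freqs: np.ndarray, n_alleles: np.ndarray, model: KinshipModel,
                    n_reps: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(g1, g2, n_ibd) with genotypes (n_reps, L, 2) under the k-vector model."""
    L = freqs.shape[0]
    g1 = np.stack([_draw_alleles(freqs, (n_reps, L), rng) for _ in range(2)], axis=-1)
    u = rng.random((n_reps, L))
    n_ibd = (u >= model.k[0]).astype(np.int64) + (u >= model.k[0] + model.k[1])
    # which allele of g1 is transmitted when exactly one is IBD
    pick = rng.integers(0, 2, size=(n_reps, L))
    na = np.broadcast_to(n_alleles, (n_reps, L))
    first = _mutate(np.take_along_axis(g1, pick[..., None], axis=-1)[..., 0], na, model.mu, rng)
    second = _mutate(np.take_along_axis(g1, (1 - pick)[..., None], axis=-1)[..., 0],
                     na, model.mu, rng)
    rand1 = _draw_alleles(freqs, (n_reps, L), rng)
    rand2 = _draw_alleles(freqs, (n_reps, L), rng)
    allele_a = np.where(n_ibd >= 1, first, rand1)
    allele_b = np.where(n_ibd == 2, second, rand2)
    return g1, np.stack([allele_a, allele_b], axis=-1), n_ibd


def simulate_related_pair(ft: FrequencyTable, model: KinshipModel, seed: int,
                          population: str | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One genotype pair (each (L, 2)) related according to ``model``.

    g1 is drawn under HWE; at each locus the IBD state is drawn from
    (k0, k1, k2) and g2 copies 0/1/2 alleles of g1 (mutation applied to
    copied alleles) with the remainder drawn from the frequencies.
    """
    population = population or ft.populations[0]
    freqs, n_alleles, avail = _pop_freqs(ft, population)
    if not avail.all():
        raise ValidationError("frequency table has unavailable loci for this population")
    rng = np.random.default_rng(seed)
    g1, g2, _ = _simulate_pairs(freqs, n_alleles, model, 1, rng)
    return g1[0], g2[0]


@dataclass
class LRSimulationResult:
    """Monte-Carlo panel log10(LR) distribution for one relationship model."""

    model: KinshipModel
    tested_hypothesis: KinshipModel
    n_reps: int
    seed: int
    log10_lr: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(self.log10_lr.mean())

    @property
    def sd(self) -> float | None:
        if self.n_reps < 2:
            return None  # undefined, by convention, not 0
        return float(self.log10_lr.std(ddof=1))

    @property
    def min(self) -> float:
        return float(self.log10_lr.min())

    @property
    def max(self) -> float:
        return float(self.log10_lr.max())

    def summary(self) -> dict:
        return {
            "model": self.model.name,
            "tested_hypothesis": self.tested_hypothesis.name,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "mean_log10_lr": self.mean,
            "sd_log10_lr": self.sd,
            "min_log10_lr": self.min,
            "max_log10_lr": self.max,
        }


def simulate_lr_distribution(ft: FrequencyTable, model: KinshipModel,
                             tested_hypothesis: KinshipModel | None = None,
                             n_reps: int = 2000, seed: int = 0,
                             population: str | None = None) -> LRSimulationResult:
    """Simulate ``n_reps`` genotype pairs under ``model`` and score each with
    ``tested_hypothesis`` (default: the generating model) against unrelated."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    tested = tested_hypothesis or model
    population = population or ft.populations[0]
    freqs, n_alleles, avail = _pop_freqs(ft, population)
    if not avail.all():
        raise ValidationError("frequency table has unavailable loci for this population")
    rng = np.random.default_rng(seed)
    g1, g2, _ = _simulate_pairs(freqs, n_alleles, model, n_reps, rng)
    lrs = _lr_core(g1, g2, freqs, n_alleles, tested)
    log10 = np.log10(lrs).sum(axis=1)
    return LRSimulationResult(model, tested, n_reps, seed, log10)


@dataclass
class SeparationReport:
    """Overlap diagnostics between a related and an unrelated LR distribution."""

    related_min: float
    related_max: float
    unrelated_min: float
    unrelated_max: float
    n_related_below_unrelated_max: int
    n_unrelated_above_related_min: int
    overlap_count: int
    misclassification_rate_at_zero: float


def separation_summary(related: LRSimulationResult,
                       unrelated: LRSimulationResult) -> SeparationReport:
    """How well a related log10(LR) distribution separates from unrelated.

    Overlap counts are replicates falling inside the other distribution's
    range; ``overlap_count`` is the larger of the two one-sided counts (0
    iff the ranges are disjoint). The misclassification rate uses the
    natural log10 LR = 0 decision threshold (related called unrelated when
    <= 0, and vice versa).
    """
    r, u = related.log10_lr, unrelated.log10_lr
    n_r = int((r <= u.max()).sum())
    n_u = int((u >= r.min()).sum())
    mis = (int((r <= 0).sum()) + int((u > 0).sum())) / (len(r) + len(u))
    return SeparationReport(
        related_min=float(r.min()), related_max=float(r.max()),
        unrelated_min=float(u.min()), unrelated_max=float(u.max()),
        n_related_below_unrelated_max=n_r,
        n_unrelated_above_related_min=n_u,
        overlap_count=max(n_r, n_u),
        misclassification_rate_at_zero=mis,
    )
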