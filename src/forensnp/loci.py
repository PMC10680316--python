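"""Core data model: loci, genotype matrices, frequency tables, depth tables.

Genotypes are stored as unordered diploid allele-index pairs in an
``(n_samples, n_loci, 2)`` int8 array; a missing call is ``(-1, -1)``.
Allele indices refer to the per-locus ``Locus.alleles`` tuple (index 0 is
the reference/first-listed allele). Loci carry 2 or 3 alleles: the panel
this package targets is autosomal and mixes diallelic and tri-allelic SNPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

MISSING = -1

#: maximum alleles per locus supported anywhere in the package
MAX_ALLELES = 3

FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Locus:
    """A diallelic or tri-allelic autosomal SNP."""

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"locus {self.id}: position must be >= 1, got {self.pos}")
        if not (2 <= len(self.alleles) <= MAX_ALLELES):
            raise ValidationError(
                f"locus {self.id}: {len(self.alleles)} alleles; only 2 or 3 supported"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"locus {self.id}: duplicate allele symbols {self.alleles}")
        object.__setattr__(self, "alleles", tuple(self.alleles))

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def is_diallelic(self) -> bool:
        return len(self.alleles) == 2


class GenotypeMatrix:
    """Diploid genotype calls for ``n_samples`` x ``n_loci``.

    Parameters
    ----------
    samples : sequence of unique sample ids
    loci : sequence of :class:`Locus`
    calls : int array, shape (N, L, 2)
        Unordered allele-index pairs; ``(-1, -1)`` marks a missing call.
    """

    def __init__(self, samples: Sequence[str], loci: Sequence[Locus], calls: np.ndarray):
        samples = list(samples)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if len(samples) < 1 or len(loci) < 1:
            raise ValidationError("genotype matrix needs at least one sample and one locus")
        if len(set(samples)) != len(samples):
            raise ValidationError("sample ids are not unique")
        if calls.shape != (len(samples), len(loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} != ({len(samples)}, {len(loci)}, 2)"
            )
        # a call is missing iff both allele slots are -1
        half_missing = (calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValidationError("half-missing calls are not allowed")
        n_alleles = np.array([loc.n_alleles for loc in loci], dtype=np.int8)
        bad = (calls >= n_alleles[None, :, None]) | (calls < MISSING)
        if bad.any():
            s, l, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"call for sample {samples[s]} at locus {loci[l].id} uses an undeclared allele"
            )
        calls = np.sort(calls, axis=2)  # calls are unordered pairs; canonicalize
        self.samples = samples
        self.loci = loci
        self.calls = calls

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    # -- masks and rates ------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def het_mask(self) -> np.ndarray:
        """Boolean (N, L): True where the call is heterozygous (and present)."""
        return (self.calls[:, :, 0] != self.calls[:, :, 1]) & ~self.missing_mask()

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def locus_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- views ----------------------------------------------------------
    def column(self, j: int) -> np.ndarray:
        """Genotype column for locus index ``j``: (N, 2) allele indices."""
        return self.calls[:, j, :]

    def subset(self, sample_idx: Sequence[int] | None = None,
               locus_idx: Sequence[int] | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        if si.size == 0 or li.size == 0:
            raise ValidationError("subset would be empty")
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.loci[j] for j in li],
            self.calls[np.ix_(si, li)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and bool(np.array_equal(self.calls, other.calls))
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_loci} loci>"


class FrequencyTable:
    """Per-locus allele-frequency vectors for one or more populations.

    ``freqs`` has shape (P, L, MAX_ALLELES); entries beyond a locus's allele
    count are zero. A (population, locus) combination with no data is marked
    unavailable by an all-NaN vector. ``n_samples`` holds per-(population,
    locus) diploid counts (NaN where unknown).
    """

    def __init__(self, populations: Sequence[str], loci: Sequence[Locus],
                 freqs: np.ndarray, n_samples: np.ndarray | None = None):
        populations = list(populations)
        loci = list(loci)
        freqs = np.asarray(freqs, dtype=float)
        if len(set(populations)) != len(populations):
            raise ValidationError("population labels are not unique")
        if freqs.shape != (len(populations), len(loci), MAX_ALLELES):
            raise ValidationError(
                f"freqs shape {freqs.shape} != ({len(populations)}, {len(loci)}, {MAX_ALLELES})"
            )
        if n_samples is None:
            n_samples = np.full((len(populations), len(loci)), np.nan)
        n_samples = np.asarray(n_samples, dtype=float)
        if n_samples.shape != (len(populations), len(loci)):
            raise ValidationError("n_samples shape mismatch")
        avail = ~np.isnan(freqs).all(axis=2)
        for p, l in np.argwhere(avail):
            vec = freqs[p, l, : loci[l].n_alleles]
            if np.isnan(vec).any() or (vec < 0).any():
                raise ValidationError(
                    f"locus {loci[l].id}, population {populations[p]}: invalid frequency vector"
                )
            if abs(vec.sum() - 1.0) > FREQ_SUM_TOL:
                raise ValidationError(
                    f"locus {loci[l].id}, population {populations[p]}: "
                    f"frequencies sum to {vec.sum():.12f}, not 1"
                )
            if freqs[p, l, loci[l].n_alleles:].any():
                raise ValidationError(
                    f"locus {loci[l].id}, population {populations[p]}: "
                    "nonzero frequency for undeclared allele"
                )
        self.populations = populations
        self.loci = loci
        self.freqs = freqs
        self.n_samples = n_samples

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise ValidationError(f"unknown population {label!r}") from None

    def available(self) -> np.ndarray:
        """Boolean (P, L): True where a frequency vector exists."""
        return ~np.isnan(self.freqs).all(axis=2)

    def freq(self, population: str, locus_id: str) -> np.ndarray:
        p = self.pop_index(population)
        l = self.locus_ids.index(locus_id)
        return self.freqs[p, l, : self.loci[l].n_alleles]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return (
            self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.freqs, other.freqs, equal_nan=True)
            and np.array_equal(self.n_samples, other.n_samples, equal_nan=True)
        )


@dataclass
class DepthTable:
    """Per-(sample, locus, allele) read depths, aligned to a GenotypeMatrix.

    ``depths`` is (N, L, MAX_ALLELES) int32, -1 where no depth was recorded.
    """

    samples: list[str]
    loci: list[Locus]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.depths.shape != (len(self.samples), len(self.loci), MAX_ALLELES):
            raise ValidationError("depth array shape mismatch")
        if (self.depths < -1).any():
            raise ValidationError("negative depths")


def allele_counts(column: np.ndarray, n_alleles: int) -> np.ndarray:
    """Count alleles in a genotype column (N, 2), ignoring missing calls."""
    obs = column[column[:, 0] != MISSING]
    return np.bincount(obs.ravel(), minlength=n_alleles)[:n_alleles]


def column_frequencies(column: np.ndarray, n_alleles: int) -> tuple[np.ndarray, int]:
    """Allele frequencies and the diploid count they are based on."""
    counts = allele_counts(column, n_alleles)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no non-missing calls at locus")
    return counts / total, int(total // 2)
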