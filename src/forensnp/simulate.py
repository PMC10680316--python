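"""Synthetic-data generators with the statistical structure the analyses assume.

The generators provide every input the pipeline needs without external data:

* multi-population allele frequencies under the Balding–Nichols model, where
  each population's frequency at a locus is Beta-distributed around an
  ancestral frequency with differentiation parameter F — so F is a known
  ground truth recoverable by F_ST, f-statistics, I_n and PCA;
* Hardy–Weinberg genotype matrices drawn from a frequency table;
* genotype pairs related by explicit pedigree simulation (parent-child,
  full sibling, half sibling, grandparent-grandchild) with Mendelian
  transmission and mutation — an independent cross-check for the
  IBD-coefficient kinship engine;
* random panel degradation at a given locus detection rate.

All generators are bit-reproducible under a fixed seed. Defaults mirror the
1993-SNP panel this package was built around: ~2% tri-allelic loci
(40/1946), mutation rate 1.29e-8 per meiosis per locus, loci spread over
the 22 autosomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import EmptyResultError, ValidationError
from .kinship import DEFAULT_MU
from .loci import MAX_ALLELES, FrequencyTable, GenotypeMatrix, Locus

TRI_ALLELIC_FRACTION_DEFAULT = 40 / 1946


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic generators."""

    n_loci: int = 1000
    populations: tuple[str, ...] = ("POP1",)
    n_per_pop: int = 100
    F: float | Mapping[str, float] = 0.0
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    tri_allelic_fraction: float = TRI_ALLELIC_FRACTION_DEFAULT
    mu: float = DEFAULT_MU
    detection_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"ancestral_maf_range must lie in (0, 0.5]: {self.ancestral_maf_range}")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValidationError(f"detection_rate must be in (0, 1]: {self.detection_rate}")
        if not 0.0 <= self.tri_allelic_fraction <= 1.0:
            raise ValidationError("tri_allelic_fraction must be in [0, 1]")
        for f in self._f_values():
            if not 0.0 <= f < 1.0:
                raise ValidationError(f"F must be in [0, 1), got {f}")

    def _f_values(self) -> list[float]:
        if isinstance(self.F, Mapping):
            return [self.F[p] for p in self.populations]
        return [self.F] * len(self.populations)


_ALLELES = ("A", "C", "G")


def _panel_loci(n_loci: int, tri_mask: np.ndarray) -> list[Locus]:
    loci = []
    for i in range(n_loci):
        n_all = 3 if tri_mask[i] else 2
        loci.append(Locus(f"snp{i:05d}", str(i % 22 + 1), 10_000 * (i // 22 + 1),
                          _ALLELES[:n_all]))
    return loci


def sample_balding_nichols_freqs(cfg: SyntheticConfig) -> FrequencyTable:
    """Per-population allele frequencies under the Balding–Nichols model.

    The ancestral minor-allele frequency is uniform on
    ``ancestral_maf_range`` and assigned to a random one of the two alleles;
    each population then draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) (Dirichlet for tri-allelic loci), so the
    expected Hudson F_ST between populations equals F. F = 0 copies the
    ancestral frequencies exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    n_tri = int(round(cfg.tri_allelic_fraction * L))
    tri_mask = np.zeros(L, dtype=bool)
    if n_tri:
        tri_mask[rng.choice(L, size=n_tri, replace=False)] = True
    loci = _panel_loci(L, tri_mask)
    maf = rng.uniform(*cfg.ancestral_maf_range, size=L)
    flip = rng.random(L) < 0.5
    anc = np.zeros((L, MAX_ALLELES))
    anc[:, 0] = np.where(flip, maf, 1.0 - maf)
    anc[:, 1] = 1.0 - anc[:, 0]
    if n_tri:
        anc[tri_mask, :] = rng.dirichlet(np.ones(3), size=n_tri)
    freqs = np.zeros((len(cfg.populations), L, MAX_ALLELES))
    for p, f in enumerate(cfg._f_values()):
        if f == 0.0:
            freqs[p] = anc
            continue
        conc = (1.0 - f) / f
        for l, loc in enumerate(loci):
            a = anc[l, : loc.n_alleles] * conc
            vec = rng.dirichlet(a)
            # guard against exactly-fixed draws so HWE probabilities stay positive
            vec = np.clip(vec, 1e-12, None)
            vec = vec / vec.sum()
            freqs[p, l, : loc.n_alleles] = vec
    return FrequencyTable(list(cfg.populations), loci, freqs)


def generate_population_genotypes(ft: FrequencyTable, n_per_pop: int | Mapping[str, int],
                                  seed: int = 0
                                  ) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Draw HWE genotypes per population from a frequency table.

    Returns the combined matrix and the sample -> population map.
    """
    rng = np.random.default_rng(seed)
    if not ft.available().all():
        raise ValidationError("frequency table has unavailable cells")
    sizes = ({p: int(n_per_pop) for p in ft.populations}
             if not isinstance(n_per_pop, Mapping) else dict(n_per_pop))
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    blocks = []
    for p, pop in enumerate(ft.populations):
        n = sizes[pop]
        if n < 1:
            raise ValidationError(f"population {pop}: n must be >= 1")
        cdf = np.cumsum(ft.freqs[p], axis=-1)
        u = rng.random((n, ft.n_loci, 2))
        calls = (u[..., None] >= cdf[None, :, None, :]).sum(axis=-1).astype(np.int8)
        blocks.append(calls)
        for i in range(n):
            sid = f"{pop}_{i:04d}"
            samples.append(sid)
            pop_of[sid] = pop
    gm = GenotypeMatrix(samples, ft.loci, np.concatenate(blocks, axis=0))
    return gm, pop_of


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _hwe_individual(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(freqs, axis=-1)
    u = rng.random((freqs.shape[0], 2))
    return (u[..., None] >= cdf[:, None, :]).sum(axis=-1).astype(np.int64)


def _transmit(parent: np.ndarray, n_alleles: np.ndarray, mu: float,
              rng: np.random.Generator) -> np.ndarray:
    """One gamete: a uniformly chosen parental allele, possibly mutated."""
    pick = rng.integers(0, 2, size=parent.shape[0])
    allele = np.take_along_axis(parent, pick[:, None], axis=1)[:, 0]
    if mu > 0:
        hit = rng.random(allele.shape) < mu
        shift = 1 + np.floor(rng.random(allele.shape) * (n_alleles - 1)).astype(np.int64)
        allele = np.where(hit, (allele + shift) % n_alleles.astype(np.int64), allele)
    return allele


def generate_pedigree_pair(ft: FrequencyTable, relationship: str, seed: int = 0,
                           mu: float = DEFAULT_MU, population: str | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """A genotype pair produced by explicit pedigree simulation.

    Founders are drawn under HWE and alleles transmitted Mendelianly with
    per-meiosis mutation rate ``mu``: PC directly, FS via two shared
    parents, HS via one shared parent, GG via a three-generation chain.
    This is the model-independent counterpart of the IBD k-vector
    simulator in :mod:`forensnp.kinship`.
    """
    rel = relationship.upper()
    if rel not in {"PC", "FS", "HS", "GG"}:
        raise ValidationError(f"unknown relationship {relationship!r}")
    population = population or ft.populations[0]
    p = ft.pop_index(population)
    if not ft.available()[p].all():
        raise ValidationError("frequency table has unavailable loci")
    freqs = ft.freqs[p]
    n_alleles = np.array([loc.n_alleles for loc in ft.loci], dtype=np.int64)
    rng = np.random.default_rng(seed)
    draw = lambda: _hwe_individual(freqs, rng)
    child = lambda pa, pb: np.stack([_transmit(pa, n_alleles, mu, rng),
                                     _transmit(pb, n_alleles, mu, rng)], axis=1)
    if rel == "PC":
        parent, mate = draw(), draw()
        return parent, child(parent, mate)
    if rel == "FS":
        pa, pb = draw(), draw()
        return child(pa, pb), child(pa, pb)
    if rel == "HS":
        shared, m1, m2 = draw(), draw(), draw()
        return child(shared, m1), child(shared, m2)
    grand, m1 = draw(), draw()
    parent = child(grand, m1)
    m2 = draw()
    return grand, child(parent, m2)


# ---------------------------------------------------------------------------
# panel degradation
# ---------------------------------------------------------------------------

def degrade_panel(gm_or_loci, detection_rate: float, seed: int = 0,
                  mode: Literal["random", "best"] = "random"):
    """Subset a panel to ``round(detection_rate * L)`` loci.

    ``mode="random"`` draws a uniform random subset (original order kept);
    ``mode="best"`` keeps the first loci of the given ordering, for callers
    that pass loci pre-sorted by a power statistic. Accepts a
    GenotypeMatrix (returns a subset matrix) or a sequence of locus
    ids/objects (returns a sublist).
    """
    if not 0.0 < detection_rate <= 1.0:
        raise ValidationError(f"detection_rate must be in (0, 1]: {detection_rate}")
    if isinstance(gm_or_loci, GenotypeMatrix):
        L = gm_or_loci.n_loci
    else:
        gm_or_loci = list(gm_or_loci)
        L = len(gm_or_loci)
    size = int(round(detection_rate * L))
    if size == 0:
        raise EmptyResultError(f"detection rate {detection_rate} keeps 0 of {L} loci")
    if mode == "best":
        idx = np.arange(size)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(L, size=size, replace=False))
    else:
        raise ValidationError(f"unknown degradation mode {mode!r}")
    if isinstance(gm_or_loci, GenotypeMatrix):
        return gm_or_loci.subset(locus_idx=idx)
    return [gm_or_loci[i] for i in idx]
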