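"""Population-structure statistics: Hudson F_ST, outgroup-f3, f4 with block
jackknife, Rosenberg informativeness for assignment, PCA with least-squares
projection, and neighbor-joining trees from F_ST distance matrices.

All f-statistics operate on per-population allele-frequency tables. Hudson's
F_ST estimator is combined across loci as a ratio of averages; standard
errors and Z-scores come from a weighted delete-one-block jackknife (blocks
default to one per chromosome). Tri-allelic loci are collapsed to a
major-allele-vs-rest diallelic encoding by default (or excluded).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .loci import MISSING, FrequencyTable, GenotypeMatrix, Locus, allele_counts


# ---------------------------------------------------------------------------
# blocks and jackknife
# ---------------------------------------------------------------------------

def assign_blocks(loci: Sequence[Locus], scheme: str | int = "chrom") -> np.ndarray:
    """Block labels per locus: ``"chrom"`` for one block per chromosome, or
    an integer for consecutive fixed-size blocks."""
    if scheme == "chrom":
        chroms = list(dict.fromkeys(loc.chrom for loc in loci))
        idx = {c: i for i, c in enumerate(chroms)}
        return np.array([idx[loc.chrom] for loc in loci])
    size = int(scheme)
    if size < 1:
        raise ValidationError(f"block size must be >= 1, got {scheme}")
    return np.arange(len(loci)) // size


def block_jackknife(numerators: np.ndarray, block_ids: np.ndarray,
                    denominators: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    The full estimate is sum(num)/sum(den) (a plain mean when denominators
    are omitted). Blocks may be unequal; weighting follows the standard
    Busing-style weighted jackknife, which reduces to the classic
    delete-one formula for equal blocks. Returns (estimate, se).
    """
    num = np.asarray(numerators, dtype=float)
    den = np.ones_like(num) if denominators is None else np.asarray(denominators, dtype=float)
    blocks = np.unique(block_ids)
    g = len(blocks)
    if g < 2:
        raise ValidationError("block jackknife needs >= 2 blocks")
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        raise UndefinedStatisticError("jackknife denominator is zero")
    theta = tot_n / tot_d
    n = len(num)
    m = np.array([(block_ids == b).sum() for b in blocks], dtype=float)
    theta_j = np.empty(g)
    for i, b in enumerate(blocks):
        mask = block_ids == b
        d = tot_d - den[mask].sum()
        if d == 0:
            raise UndefinedStatisticError(f"deleting block {b} empties the denominator")
        theta_j[i] = (tot_n - num[mask].sum()) / d
    h = n / m
    theta_dot = g * theta - np.sum((1.0 - m / n) * theta_j)
    tau = h * theta - (h - 1.0) * theta_j
    var = np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / g
    return float(theta), float(math.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class FStat:
    """A point estimate with block-jackknife uncertainty."""

    kind: Literal["FST", "F3", "F4"]
    populations: tuple[str, ...]
    value: float
    se: float
    z: float
    n_blocks: int
    n_snps: int

    def to_dict(self) -> dict:
        return {"kind": self.kind, "populations": list(self.populations),
                "value": self.value, "se": self.se,
                "z": None if math.isnan(self.z) else self.z,
                "n_blocks": self.n_blocks, "n_snps": self.n_snps}


def _make_fstat(kind, pops, num, den, block_ids) -> FStat:
    est, se = block_jackknife(num, block_ids, den)
    z = est / se if se > 0 else math.nan
    return FStat(kind, tuple(pops), est, se, z, len(np.unique(block_ids)), len(num))


# ---------------------------------------------------------------------------
# diallelic views of a frequency table
# ---------------------------------------------------------------------------

def _collapsed_freqs(ft: FrequencyTable, exclude_triallelic: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(P, L) frequency of one reference allele per locus, and a locus mask.

    Diallelic loci use allele 0; tri-allelic loci are collapsed to their
    globally most frequent allele vs the rest (or masked out entirely when
    ``exclude_triallelic``). NaN marks unavailable (population, locus) cells.
    """
    P, L = len(ft.populations), ft.n_loci
    out = np.full((P, L), np.nan)
    mask = np.ones(L, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(ft.freqs, axis=0)
    for l, loc in enumerate(ft.loci):
        if loc.is_diallelic:
            out[:, l] = ft.freqs[:, l, 0]
        elif exclude_triallelic:
            mask[l] = False
        else:
            out[:, l] = ft.freqs[:, l, int(np.argmax(mean[l]))]
    return out, mask


def _haploid_sizes(ft: FrequencyTable) -> np.ndarray:
    return 2.0 * ft.n_samples


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def hudson_fst_components(p1, p2, n1, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Hudson numerator/denominator.

    ``n1``/``n2`` are haploid sample sizes; NaN sizes are treated as
    population (infinite-sample) frequencies, dropping the finite-sample
    correction for that side.
    """
    c1 = np.where(np.isnan(n1), 0.0, p1 * (1 - p1) / np.where(np.isnan(n1), 1.0, n1 - 1.0))
    c2 = np.where(np.isnan(n2), 0.0, p2 * (1 - p2) / np.where(np.isnan(n2), 1.0, n2 - 1.0))
    num = (p1 - p2) ** 2 - c1 - c2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_pair(ft: FrequencyTable, pop1: str, pop2: str,
                    blocks: str | int = "chrom",
                    exclude_triallelic: bool = False) -> FStat:
    """Hudson F_ST between two populations, ratio of averages across loci,
    with a block-jackknife standard error."""
    p, mask = _collapsed_freqs(ft, exclude_triallelic)
    n = _haploid_sizes(ft)
    i, j = ft.pop_index(pop1), ft.pop_index(pop2)
    usable = mask & ~np.isnan(p[i]) & ~np.isnan(p[j])
    finite_n = ~np.isnan(n[i]) & ~np.isnan(n[j])
    usable &= np.where(finite_n, (n[i] >= 2) & (n[j] >= 2), True)
    if not usable.any():
        raise UndefinedStatisticError(f"no usable loci for ({pop1}, {pop2})")
    u = np.flatnonzero(usable)
    num, den = hudson_fst_components(p[i, u], p[j, u], n[i, u], n[j, u])
    if den.sum() == 0:
        raise UndefinedStatisticError(
            f"both populations fixed at every usable locus ({pop1}, {pop2})")
    block_ids = assign_blocks(ft.loci, blocks)[u]
    if len(np.unique(block_ids)) < 2:
        block_ids = assign_blocks([ft.loci[k] for k in u], max(1, len(u) // 20))
    return _make_fstat("FST", (pop1, pop2), num, den, block_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise F_ST matrix with zero diagonal.

    Small negative estimates (unbiased-estimator noise) are kept; they are
    clamped to zero only when the matrix feeds tree building.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def group_means(self, focal: str, grouping: Mapping[str, str]) -> dict[str, float]:
        """Mean distance from ``focal`` to each group of populations."""
        i = self.labels.index(focal)
        out: dict[str, list[float]] = {}
        for j, lab in enumerate(self.labels):
            if lab == focal or lab not in grouping:
                continue
            out.setdefault(grouping[lab], []).append(self.values[i, j])
        return {g: float(np.mean(v)) for g, v in out.items()}


def fst_matrix(ft: FrequencyTable, blocks: str | int = "chrom",
               exclude_triallelic: bool = False) -> DistanceMatrix:
    """All pairwise Hudson F_ST values."""
    P = len(ft.populations)
    if P < 2:
        raise ValidationError("F_ST matrix needs >= 2 populations")
    vals = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            f = hudson_fst_pair(ft, ft.populations[i], ft.populations[j],
                                blocks, exclude_triallelic)
            vals[i, j] = vals[j, i] = f.value
    return DistanceMatrix(list(ft.populations), vals)


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

def _fstat_freqs(ft, labels, blocks, exclude_triallelic):
    p, mask = _collapsed_freqs(ft, exclude_triallelic)
    idx = [ft.pop_index(lab) for lab in labels]
    usable = mask.copy()
    for i in idx:
        usable &= ~np.isnan(p[i])
    if not usable.any():
        raise UndefinedStatisticError(f"no usable loci for {labels}")
    u = np.flatnonzero(usable)
    block_ids = assign_blocks(ft.loci, blocks)[u]
    if len(np.unique(block_ids)) < 2:
        raise ValidationError("insufficient loci for >= 2 jackknife blocks")
    return p, idx, u, block_ids


def outgroup_f3(ft: FrequencyTable, outgroup: str, a: str, b: str,
                blocks: str | int = "chrom", corrected: bool = True,
                exclude_triallelic: bool = False) -> FStat:
    """Outgroup-f3(outgroup; a, b): shared drift of a and b relative to the
    outgroup, averaged over loci.

    The outgroup's finite-sample heterozygosity correction
    o(1-o)/(n_o - 1) is subtracted per locus when ``corrected`` (requires
    the outgroup's sample sizes in the table).
    """
    if len({outgroup, a, b}) != 3:
        raise ValidationError("f3 needs three distinct populations")
    p, (io, ia, ib), u, block_ids = _fstat_freqs(ft, (outgroup, a, b), blocks,
                                                 exclude_triallelic)
    o, pa, pb = p[io, u], p[ia, u], p[ib, u]
    num = (o - pa) * (o - pb)
    if corrected:
        n_o = _haploid_sizes(ft)[io, u]
        if np.isnan(n_o).any():
            raise ValidationError(
                "outgroup sample sizes required for the heterozygosity correction")
        num = num - o * (1 - o) / (n_o - 1.0)
    return _make_fstat("F3", (outgroup, a, b), num, None, block_ids)


def f4_stat(ft: FrequencyTable, o: str, k: str, x: str, y: str,
            blocks: str | int = "chrom", exclude_triallelic: bool = False) -> FStat:
    """f4(o, k; x, y) = mean over loci of (o - k)(x - y).

    A significantly negative value (|Z| above the caller's cutoff) indicates
    gene flow between the test population k and x; positive, with y.
    """
    p, (io, ik, ix, iy), u, block_ids = _fstat_freqs(ft, (o, k, x, y), blocks,
                                                     exclude_triallelic)
    num = (p[io, u] - p[ik, u]) * (p[ix, u] - p[iy, u])
    return _make_fstat("F4", (o, k, x, y), num, None, block_ids)


# ---------------------------------------------------------------------------
# informativeness for assignment
# ---------------------------------------------------------------------------

@dataclass
class InformativenessResult:
    """Per-locus Rosenberg I_n for one population grouping."""

    grouping_label: str
    values: pd.Series  # indexed by locus id
    threshold: float
    selected: list[str]
    skipped: list[str]
    n_groups: int = 0


def informativeness_in(ft: FrequencyTable, grouping: Mapping[str, str],
                       threshold: float = 0.1,
                       grouping_label: str = "grouping") -> InformativenessResult:
    """Rosenberg's informativeness for assignment, per locus.

    Group allele frequencies are unweighted means of member-population
    frequencies. With K groups and group frequencies p_ij (group i, allele
    j), I_n = sum_j [ -pbar_j ln pbar_j + (1/K) sum_i p_ij ln p_ij ] with
    0 ln 0 := 0 and pbar the unweighted mean over groups. Loci missing a
    frequency for any group are skipped and reported.
    """
    groups = sorted(set(grouping.values()))
    K = len(groups)
    if K < 2:
        raise ValidationError("informativeness needs >= 2 groups")
    members = {g: [ft.pop_index(p) for p in grouping if grouping[p] == g] for g in groups}
    avail = ft.available()
    vals: dict[str, float] = {}
    skipped: list[str] = []
    for l, loc in enumerate(ft.loci):
        ok = all(avail[i, l] for g in groups for i in members[g])
        if not ok:
            skipped.append(loc.id)
            continue
        pg = np.stack([ft.freqs[members[g], l, :].mean(axis=0) for g in groups])
        pbar = pg.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(pbar > 0, -pbar * np.log(pbar), 0.0)
            t2 = np.where(pg > 0, pg * np.log(pg), 0.0).sum(axis=0) / K
        vals[loc.id] = float(np.sum(t1 + t2))
    series = pd.Series(vals, name="I_n")
    return InformativenessResult(grouping_label, series, threshold,
                                 [lid for lid, v in vals.items() if v > threshold],
                                 skipped, n_groups=K)


# ---------------------------------------------------------------------------
# PCA with projection
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of a standardized genotype matrix.

    ``coords`` holds per-sample coordinates (fitted samples and projected
    samples alike); eigenvalues are non-increasing. ``p_hat`` and ``scale``
    record the per-locus normalization so new samples can be projected.
    """

    coords: pd.DataFrame
    loadings: np.ndarray
    eigenvalues: np.ndarray
    p_hat: np.ndarray
    scale: np.ndarray
    locus_ids: list[str]
    fit_samples: list[str]
    projected_samples: list[str]


def _dosage_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """(N, L) counts of each locus's non-reference side; NaN where missing.

    Tri-allelic loci are collapsed: the dosage counts alleles other than the
    locus's overall most frequent allele.
    """
    dos = np.full((gm.n_samples, gm.n_loci), np.nan)
    for j, loc in enumerate(gm.loci):
        counts = allele_counts(gm.column(j), loc.n_alleles)
        major = int(np.argmax(counts)) if not loc.is_diallelic else 0
        col = gm.column(j)
        ok = col[:, 0] != MISSING
        dos[ok, j] = (col[ok] != major).sum(axis=1)
    return dos


def pca_fit_project(gm: GenotypeMatrix, fit_samples: Sequence[str],
                    project_samples: Sequence[str] | None = None,
                    n_components: int = 10) -> PCAResult:
    """PCA in the EIGENSOFT normalization, with least-squares projection.

    Dosages are centered by 2*p_hat and scaled by sqrt(p_hat(1-p_hat)) with
    p_hat = (1 + allele count)/(2 + 2*N_fit) computed on the fit set;
    missing entries contribute zero after centering. Samples outside the
    fit set are placed by least squares on their non-missing standardized
    entries. No outlier iteration is performed.
    """
    fit_samples = list(fit_samples)
    project_samples = list(project_samples or [])
    if len(fit_samples) < 2:
        raise ValidationError("PCA needs >= 2 fit samples")
    sidx = {s: i for i, s in enumerate(gm.samples)}
    for s in fit_samples + project_samples:
        if s not in sidx:
            raise ValidationError(f"unknown sample {s!r}")
    dos = _dosage_matrix(gm)
    fi = np.array([sidx[s] for s in fit_samples])
    X = dos[fi]
    obs = ~np.isnan(X)
    cnt = np.nansum(X, axis=0)
    n_obs = obs.sum(axis=0)
    p_hat = (1.0 + cnt) / (2.0 + 2.0 * n_obs)
    keep = ~np.isclose(np.nanvar(X, axis=0), 0.0) & (n_obs > 0)
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 polymorphic loci in the fit set")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant loci before PCA",
                      stacklevel=2)
    p_hat = p_hat[keep]
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    Z = (X[:, keep] - 2.0 * p_hat) / scale
    Z = np.nan_to_num(Z)
    k = min(n_components, min(Z.shape))
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    eigenvalues = S ** 2 / (len(fit_samples) - 1)
    coords = {s: U[i] * S for i, s in enumerate(fit_samples)}
    V = Vt.T  # (L', k)
    for s in project_samples:
        x = (dos[sidx[s], keep] - 2.0 * p_hat) / scale
        m = ~np.isnan(x)
        if not m.any():
            raise ValidationError(f"sample {s!r} has no observed loci to project")
        sol, *_ = np.linalg.lstsq(V[m], x[m], rcond=None)
        coords[s] = sol
    names = [f"PC{i + 1}" for i in range(k)]
    frame = pd.DataFrame.from_dict(coords, orient="index", columns=names)
    return PCAResult(frame, V, eigenvalues, p_hat, scale,
                     [loc.id for loc, kp in zip(gm.loci, keep) if kp],
                     fit_samples, project_samples)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """An unrooted tree over population labels, Newick-serializable."""

    newick: str

    def to_skbio(self):
        from io import StringIO

        from skbio import TreeNode
        return TreeNode.read(StringIO(self.newick))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        return cls(newick.strip())

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.to_skbio().tips()}


def nj_tree(dm: DistanceMatrix) -> Phylogeny:
    """Saitou–Nei neighbor joining on an F_ST (or any) distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch; negative input distances are clamped to zero before
    clustering. Join choices break ties by sorted label pair, so the result
    is invariant to input label order.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValidationError("NJ needs >= 3 taxa")
    D = {a: {b: max(0.0, dm.values[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    node_repr = {a: a for a in labels}  # label -> newick fragment
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for ai in range(n):
            for bi in range(ai + 1, n):
                a, b = active[ai], active[bi]
                q = (n - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = D[a][b] - la
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        new = f"__internal{counter}"
        counter += 1
        node_repr[new] = f"({node_repr[a]}:{la:.10g},{node_repr[b]}:{lb:.10g})"
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = D[c][new] = max(0.0, d)
        D[new][new] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [new])
    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    la, lb, lc = (max(0.0, v) for v in (la, lb, lc))
    newick = (f"({node_repr[a]}:{la:.10g},{node_repr[b]}:{lb:.10g},"
              f"{node_repr[c]}:{lc:.10g});")
    return Phylogeny(newick)
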