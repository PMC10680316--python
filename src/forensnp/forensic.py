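"""Per-locus forensic parameters, HWE/LD screening, and cumulative panel power.

The per-locus bundle follows standard forensic-genetics definitions:

* observed heterozygosity ``Hobs`` — heterozygous fraction of non-missing calls;
* gene diversity ``GD`` — the unbiased estimator (n/(n-1))(1 - sum p_j^2)
  over n sampled alleles;
* match probability ``PM`` — sum of squared observed genotype-class
  proportions, with power of discrimination ``PD = 1 - PM``;
* power of exclusion ``PE`` — Brenner's trio-exclusion formula
  h^2 (1 - 2 h H^2) with h = Hobs and H = 1 - h;
* an exact conditional Hardy–Weinberg test (full enumeration, with a seeded
  Monte-Carlo fallback for large tri-allelic tables);
* EM-based haplotype-frequency r^2 between diallelic loci.

Cumulative 1-CPD and 1-CPE panel curves are accumulated as sums of natural
logs so the products survive underflow well below 1e-308.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (UndefinedStatisticError, UnsupportedLocusError,
                     ValidationError)
from .loci import (MISSING, GenotypeMatrix, Locus, allele_counts,
                   column_frequencies)

# ---------------------------------------------------------------------------
# scalar per-locus statistics
# ---------------------------------------------------------------------------

def observed_heterozygosity(column: np.ndarray) -> float:
    """Fraction of non-missing diploid calls that are heterozygous."""
    ok = column[:, 0] != MISSING
    if not ok.any():
        raise UndefinedStatisticError("all calls missing; Hobs undefined")
    sub = column[ok]
    return float((sub[:, 0] != sub[:, 1]).mean())


def gene_diversity(freqs: Sequence[float], n_diploids: int) -> float:
    """Unbiased gene diversity (n/(n-1))(1 - sum p^2), n = 2 * n_diploids."""
    if n_diploids < 2:
        raise ValidationError(f"gene diversity needs >= 2 diploids, got {n_diploids}")
    p = np.asarray(freqs, dtype=float)
    n = 2 * n_diploids
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def match_probability(column: np.ndarray) -> tuple[float, float]:
    """(PM, PD) from observed genotype-class proportions.

    PM is the probability that two individuals drawn at random from the
    sample share a genotype: the sum of squared class proportions.
    """
    ok = column[:, 0] != MISSING
    if not ok.any():
        raise UndefinedStatisticError("all calls missing; PM undefined")
    sub = np.sort(column[ok], axis=1)
    _, counts = np.unique(sub, axis=0, return_counts=True)
    props = counts / counts.sum()
    pm = float(np.sum(props ** 2))
    return pm, 1.0 - pm


def power_of_exclusion(hobs: float) -> float:
    """Brenner's trio-exclusion power: h^2 (1 - 2 h H^2), H = 1 - h."""
    if not 0.0 <= hobs <= 1.0:
        raise ValidationError(f"Hobs must be in [0, 1], got {hobs}")
    h = hobs
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


# ---------------------------------------------------------------------------
# exact Hardy–Weinberg tests
# ---------------------------------------------------------------------------

def hwe_exact_diallelic(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional HWE test for a diallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (two-sided, Wigginton-style). A monomorphic locus returns 1.0.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValidationError("negative genotype counts")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise ValidationError("no observations")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # probabilities over all het counts with the same parity as n_rare
    from scipy.special import gammaln

    h0 = n_rare % 2
    hets = np.arange(h0, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (hets * math.log(2.0) + gammaln(n + 1)
            - gammaln(hets + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _log_table_prob(hom: Sequence[int], het: Mapping[tuple[int, int], int],
                    allele_counts_: Sequence[int], n: int) -> float:
    """Levene's conditional probability of a genotype table given allele counts."""
    n_het = sum(het.values())
    lp = (math.lgamma(n + 1) + sum(math.lgamma(c + 1) for c in allele_counts_)
          + n_het * math.log(2.0) - math.lgamma(2 * n + 1))
    for c in hom:
        lp -= math.lgamma(c + 1)
    for c in het.values():
        lp -= math.lgamma(c + 1)
    return lp


def hwe_exact_test(genotype_counts: Mapping[tuple[int, int], int], locus: Locus,
                   seed: int = 0, mc_reps: int = 10_000,
                   max_tables: int = 2_000_000) -> float:
    """Exact conditional HWE test for a diallelic or tri-allelic locus.

    ``genotype_counts`` maps unordered allele-index pairs (i <= j) to counts.
    Diallelic loci use the closed recurrence-free enumeration; tri-allelic
    loci enumerate all genotype tables consistent with the observed allele
    counts when that is feasible (< ``max_tables`` candidate tables), else
    fall back to seeded Monte-Carlo permutation of the allele multiset.
    """
    counts = {(min(i, j), max(i, j)): int(c) for (i, j), c in genotype_counts.items() if c}
    if any(c < 0 for c in counts.values()):
        raise ValidationError("negative genotype counts")
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("no observations")
    A = locus.n_alleles
    ac = np.zeros(A, dtype=int)
    for (i, j), c in counts.items():
        if j >= A:
            raise ValidationError(f"genotype uses undeclared allele at locus {locus.id}")
        ac[i] += c
        ac[j] += c
    if (ac > 0).sum() <= 1:
        return 1.0  # monomorphic: no test possible (documented convention)
    if A == 2 or (ac > 0).sum() == 2:
        present = np.flatnonzero(ac > 0) if A == 3 else np.array([0, 1])
        a, b = present[:2]
        return hwe_exact_diallelic(counts.get((a, b), 0),
                                   counts.get((a, a), 0), counts.get((b, b), 0))
    return _hwe_exact_triallelic(counts, ac, n, seed, mc_reps, max_tables)


def _hwe_exact_triallelic(counts, ac, n, seed, mc_reps, max_tables) -> float:
    c1, c2, c3 = int(ac[0]), int(ac[1]), int(ac[2])
    approx = (min(c1, c2) + 1) * (min(c1, c3) + 1) * (min(c2, c3) + 1)
    obs_het = {(0, 1): counts.get((0, 1), 0), (0, 2): counts.get((0, 2), 0),
               (1, 2): counts.get((1, 2), 0)}
    obs_hom = [counts.get((0, 0), 0), counts.get((1, 1), 0), counts.get((2, 2), 0)]
    lp_obs = _log_table_prob(obs_hom, obs_het, (c1, c2, c3), n)
    if approx <= max_tables:
        logps = []
        for n12 in range(min(c1, c2) + 1):
            for n13 in range(min(c1 - n12, c3) + 1):
                r1 = c1 - n12 - n13
                if r1 % 2:
                    continue
                for n23 in range(min(c2 - n12, c3 - n13) + 1):
                    r2 = c2 - n12 - n23
                    r3 = c3 - n13 - n23
                    if r2 < 0 or r3 < 0 or r2 % 2 or r3 % 2:
                        continue
                    logps.append(_log_table_prob(
                        (r1 // 2, r2 // 2, r3 // 2),
                        {(0, 1): n12, (0, 2): n13, (1, 2): n23}, (c1, c2, c3), n))
        logps = np.array(logps)
        ref = logps.max()
        probs = np.exp(logps - ref)
        probs /= probs.sum()
        p_obs = math.exp(lp_obs - ref) / np.exp(logps - ref).sum()
        return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    # Monte-Carlo: permute the allele multiset and re-pair
    rng = np.random.default_rng(seed)
    alleles = np.repeat(np.arange(3), (c1, c2, c3))
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(alleles).reshape(-1, 2)
        perm.sort(axis=1)
        hom = [0, 0, 0]
        het = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        pairs, cnts = np.unique(perm, axis=0, return_counts=True)
        for (i, j), c in zip(pairs, cnts):
            if i == j:
                hom[i] = int(c)
            else:
                het[(int(i), int(j))] = int(c)
        if _log_table_prob(hom, het, (c1, c2, c3), n) <= lp_obs + 1e-12:
            hits += 1
    return (hits + 1) / (mc_reps + 1)


def hwe_test_column(column: np.ndarray, locus: Locus, seed: int = 0) -> float:
    """HWE exact test straight from a genotype column."""
    ok = column[:, 0] != MISSING
    if not ok.any():
        raise UndefinedStatisticError("all calls missing; HWE test undefined")
    sub = np.sort(column[ok], axis=1)
    pairs, cnts = np.unique(sub, axis=0, return_counts=True)
    counts = {(int(i), int(j)): int(c) for (i, j), c in zip(pairs, cnts)}
    return hwe_exact_test(counts, locus, seed=seed)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    locus1: str
    locus2: str
    r2: float
    flagged: bool


def _em_r2(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-12,
           max_iter: int = 1000) -> float | None:
    """r^2 from EM haplotype-frequency estimation on unphased dosage vectors.

    ``g1``/``g2`` hold per-sample counts (0/1/2) of one chosen allele at each
    locus. Returns None when either locus is monomorphic in the overlap.
    """
    n = len(g1)
    tab = np.zeros((3, 3))
    np.add.at(tab, (g1, g2), 1.0)
    pA = g1.sum() / (2 * n)  # freq of the counted allele at locus 1
    pB = g2.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    # haplotype counts fixed by all cells except the double heterozygote
    base = np.zeros((2, 2))  # [allele at locus1][allele at locus2], 1 = counted
    base[0, 0] = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    base[0, 1] = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    base[1, 0] = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    base[1, 1] = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    ndh = tab[1, 1]
    h = np.array([[(1 - pA) * (1 - pB), (1 - pA) * pB], [pA * (1 - pB), pA * pB]])
    for _ in range(max_iter):
        if ndh:
            cis = h[0, 0] * h[1, 1]
            trans = h[0, 1] * h[1, 0]
            w = 0.5 if cis + trans == 0 else cis / (cis + trans)
            exp = base + ndh * np.array([[w, 1 - w], [1 - w, w]])
        else:
            exp = base
        new = exp / (2 * n)
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new
    D = h[1, 1] - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def ld_r2(col1: np.ndarray, col2: np.ndarray, locus1: Locus, locus2: Locus,
          threshold: float = 0.2) -> LDResult:
    """Squared haplotype-frequency correlation between two diallelic loci.

    Haplotype frequencies are estimated by EM from unphased genotypes (the
    only ambiguity is the double heterozygote). Tri-allelic loci are not
    supported and raise :class:`UnsupportedLocusError`.
    """
    if not locus1.is_diallelic or not locus2.is_diallelic:
        raise UnsupportedLocusError(
            f"LD r^2 is defined for diallelic pairs only ({locus1.id}, {locus2.id})")
    ok = (col1[:, 0] != MISSING) & (col2[:, 0] != MISSING)
    if ok.sum() < 2:
        raise UndefinedStatisticError(
            f"fewer than 2 overlapping calls for ({locus1.id}, {locus2.id})")
    r2 = _em_r2(col1[ok].sum(axis=1), col2[ok].sum(axis=1))
    if r2 is None:
        raise UndefinedStatisticError(
            f"monomorphic locus in overlap for ({locus1.id}, {locus2.id})")
    return LDResult(locus1.id, locus2.id, r2, r2 > threshold)


# ---------------------------------------------------------------------------
# cumulative panel power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusForensicStats:
    locus_id: str
    hobs: float
    gd: float
    pm: float
    pd: float
    pe: float
    maf: float
    hwe_p: float

    def __post_init__(self) -> None:
        for name in ("hobs", "gd", "pm", "pd", "pe", "maf", "hwe_p"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{name}={v} outside [0, 1] at {self.locus_id}")
        if abs(self.pd - (1.0 - self.pm)) > 1e-12:
            raise ValidationError(f"PD != 1 - PM at {self.locus_id}")


@dataclass
class PanelDecayCurve:
    """Cumulative 1-CPD and 1-CPE as loci are added in descending order.

    ``one_minus_cpd[k]`` is the product of the k+1 largest per-locus PM
    values (analogously ``one_minus_cpe`` with 1-PE); ``log10_*`` carry the
    log-space accumulations, which remain finite past float underflow.
    """

    locus_ids: list[str]
    one_minus_cpd: np.ndarray
    one_minus_cpe: np.ndarray
    log10_one_minus_cpd: np.ndarray
    log10_one_minus_cpe: np.ndarray
    order_by: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": np.arange(1, len(self.locus_ids) + 1),
            "locus_id": self.locus_ids,
            "one_minus_cpd": self.one_minus_cpd,
            "one_minus_cpe": self.one_minus_cpe,
            "log10_one_minus_cpd": self.log10_one_minus_cpd,
            "log10_one_minus_cpe": self.log10_one_minus_cpe,
        })


def cumulative_decay(stats: Sequence[LocusForensicStats],
                     order_by: Literal["PD", "PE"] = "PD") -> PanelDecayCurve:
    """Panel power decay as loci are added best-first.

    Loci are sorted descending by the chosen statistic (ties broken by locus
    id); both curves are accumulated along that single ordering as sums of
    natural logs.
    """
    if not stats:
        raise ValidationError("no loci")
    if order_by not in ("PD", "PE"):
        raise ValidationError(f"order_by must be 'PD' or 'PE', got {order_by!r}")
    for s in stats:
        if not (0.0 <= s.pm <= 1.0 and 0.0 <= s.pe <= 1.0):
            raise ValidationError(f"PM/PE outside [0,1] at {s.locus_id}")
    key = (lambda s: (-s.pd, s.locus_id)) if order_by == "PD" else (lambda s: (-s.pe, s.locus_id))
    ordered = sorted(stats, key=key)
    pm = np.array([s.pm for s in ordered])
    one_minus_pe = np.array([1.0 - s.pe for s in ordered])
    with np.errstate(divide="ignore"):
        log_cpd = np.cumsum(np.log(pm)) / math.log(10.0)
        log_cpe = np.cumsum(np.log(one_minus_pe)) / math.log(10.0)
    return PanelDecayCurve(
        [s.locus_id for s in ordered],
        np.power(10.0, log_cpd),
        np.power(10.0, log_cpe),
        log_cpd,
        log_cpe,
        order_by,
    )


# ---------------------------------------------------------------------------
# panel-level model
# ---------------------------------------------------------------------------

def locus_summary(gm: GenotypeMatrix, hwe_seed: int = 0
                  ) -> tuple[list[LocusForensicStats], dict]:
    """Per-locus forensic statistics plus per-class medians.

    Medians are reported separately for diallelic and tri-allelic loci;
    loci that are completely homozygous or completely heterozygous are
    excluded from the median summary (but kept in the per-locus list).
    An empty class yields no median entry rather than NaN.
    """
    stats = []
    for j, loc in enumerate(gm.loci):
        col = gm.column(j)
        hobs = observed_heterozygosity(col)
        freqs, n_dip = column_frequencies(col, loc.n_alleles)
        pm, pd_ = match_probability(col)
        stats.append(LocusForensicStats(
            locus_id=loc.id,
            hobs=hobs,
            gd=gene_diversity(freqs, n_dip) if n_dip >= 2 else 0.0,
            pm=pm,
            pd=pd_,
            pe=power_of_exclusion(hobs),
            maf=float(1.0 - freqs.max()),
            hwe_p=hwe_test_column(col, loc, seed=hwe_seed),
        ))
    medians: dict[str, dict[str, float] | None] = {}
    for label, pred in (("diallelic", lambda l: l.is_diallelic),
                        ("tri_allelic", lambda l: not l.is_diallelic)):
        vals = [s for s, loc in zip(stats, gm.loci)
                if pred(loc) and 0.0 < s.hobs < 1.0]
        if not vals:
            medians[label] = None
            continue
        medians[label] = {
            "PD": float(np.median([s.pd for s in vals])),
            "GD": float(np.median([s.gd for s in vals])),
            "PM": float(np.median([s.pm for s in vals])),
            "Hobs": float(np.median([s.hobs for s in vals])),
            "PE": float(np.median([s.pe for s in vals])),
            "n_loci": len(vals),
        }
    return stats, medians


class ForensicPanel:
    """Forensic evaluation model for a QC-passed genotype matrix.

    ``fit()`` computes the per-locus statistic bundle, HWE screening with
    Bonferroni correction, optional pairwise LD screening, and returns a
    :class:`ForensicPanelResults`.
    """

    def __init__(self, gm: GenotypeMatrix):
        self.gm = gm

    def fit(self, hwe_alpha: float = 0.05, bonferroni: bool = True,
            ld_r2_threshold: float = 0.2, compute_ld: bool = False,
            seed: int = 0) -> "ForensicPanelResults":
        stats, medians = locus_summary(self.gm, hwe_seed=seed)
        threshold = hwe_alpha / self.gm.n_loci if bonferroni else hwe_alpha
        violations = [s.locus_id for s in stats if s.hwe_p < threshold]
        ld_results: list[LDResult] | None = None
        n_ld_skipped = 0
        if compute_ld:
            ld_results = []
            for x in range(self.gm.n_loci):
                for y in range(x + 1, self.gm.n_loci):
                    if not (self.gm.loci[x].is_diallelic and self.gm.loci[y].is_diallelic):
                        n_ld_skipped += 1
                        continue
                    try:
                        ld_results.append(ld_r2(self.gm.column(x), self.gm.column(y),
                                                self.gm.loci[x], self.gm.loci[y],
                                                ld_r2_threshold))
                    except UndefinedStatisticError:
                        n_ld_skipped += 1
        return ForensicPanelResults(self.gm, stats, medians, threshold, violations,
                                    ld_results, n_ld_skipped)


class ForensicPanelResults:
    """Fitted per-locus forensic statistics and panel-level summaries."""

    def __init__(self, gm, stats, medians, hwe_threshold, hwe_violations,
                 ld_results, n_ld_skipped):
        self.gm = gm
        self.stats = stats
        self.medians = medians
        self.hwe_threshold = hwe_threshold
        self.hwe_violations = hwe_violations
        self.ld_results = ld_results
        self.n_ld_skipped = n_ld_skipped

    @property
    def locus_stats(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": [s.locus_id for s in self.stats],
            "chrom": [loc.chrom for loc in self.gm.loci],
            "pos": [loc.pos for loc in self.gm.loci],
            "n_alleles": [loc.n_alleles for loc in self.gm.loci],
            "Hobs": [s.hobs for s in self.stats],
            "GD": [s.gd for s in self.stats],
            "PM": [s.pm for s in self.stats],
            "PD": [s.pd for s in self.stats],
            "PE": [s.pe for s in self.stats],
            "MAF": [s.maf for s in self.stats],
            "hwe_p": [s.hwe_p for s in self.stats],
        })

    def decay(self, order_by: Literal["PD", "PE"] = "PD") -> PanelDecayCurve:
        return cumulative_decay(self.stats, order_by=order_by)

    def flagged_ld_pairs(self) -> list[LDResult]:
        return [r for r in (self.ld_results or []) if r.flagged]

    def summary(self) -> str:
        lines = [
            f"Forensic panel: {self.gm.n_samples} samples x {self.gm.n_loci} loci",
            f"HWE violations at p < {self.hwe_threshold:.3g} (Bonferroni): "
            f"{len(self.hwe_violations)}",
        ]
        if self.ld_results is not None:
            lines.append(f"LD pairs flagged (r^2 screen): {len(self.flagged_ld_pairs())} "
                         f"of {len(self.ld_results)} tested ({self.n_ld_skipped} skipped)")
        for label, med in self.medians.items():
            if med is None:
                lines.append(f"{label}: no informative loci")
            else:
                lines.append(
                    f"{label} medians (n={med['n_loci']}): "
                    f"PD={med['PD']:.4f} GD={med['GD']:.4f} PM={med['PM']:.4f} "
                    f"Hobs={med['Hobs']:.4f} PE={med['PE']:.4f}")
        dec = self.decay("PD")
        lines.append(f"final 1-CPD = {dec.one_minus_cpd[-1]:.3g} "
                     f"(log10 = {dec.log10_one_minus_cpd[-1]:.2f})")
        lines.append(f"final 1-CPE = {dec.one_minus_cpe[-1]:.3g} "
                     f"(log10 = {dec.log10_one_minus_cpe[-1]:.2f})")
        return "\n".join(lines)
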