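"""Quality control: call-rate filtering, allele frequencies, coverage ratios,
and MAF/LD pruning.

The default call-rate thresholds are 1.0/1.0: only samples and loci with
complete calls survive, the regime a forensic panel is validated under.
Sample filtering runs before locus filtering and the two passes iterate to a
fixed point so the retained matrix always satisfies both thresholds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ValidationError
from .loci import (MAX_ALLELES, MISSING, DepthTable, FrequencyTable,
                   GenotypeMatrix, allele_counts)


@dataclass
class QCReport:
    """Accounting of a QC pass: what was removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_loci: list[tuple[str, str]] = field(default_factory=list)
    sample_call_rates: dict[str, float] = field(default_factory=dict)
    locus_call_rates: dict[str, float] = field(default_factory=dict)
    acr_summary: dict | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "removed_samples": [{"id": s, "reason": r} for s, r in self.removed_samples],
                "removed_loci": [{"id": l, "reason": r} for l, r in self.removed_loci],
                "sample_call_rates": self.sample_call_rates,
                "locus_call_rates": self.locus_call_rates,
                "acr_summary": self.acr_summary,
            },
            **kwargs,
        )


def apply_qc_filters(gm: GenotypeMatrix, min_sample_call_rate: float = 1.0,
                     min_locus_call_rate: float = 1.0) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples, then loci, by genotype call rate.

    Thresholds are fractions in [0, 1]; a sample/locus is retained when its
    call rate is >= the threshold. Passes alternate (samples first) until no
    further removal occurs, so the result is a fixed point and the operation
    is idempotent. Raises :class:`EmptyResultError` when everything would be
    removed.
    """
    for name, thr in (("min_sample_call_rate", min_sample_call_rate),
                      ("min_locus_call_rate", min_locus_call_rate)):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {thr}")
    report = QCReport(
        sample_call_rates=dict(zip(gm.samples, gm.sample_call_rates())),
        locus_call_rates=dict(zip(gm.locus_ids, gm.locus_call_rates())),
    )
    cur = gm
    while True:
        changed = False
        rates = cur.sample_call_rates()
        keep = rates >= min_sample_call_rate
        if not keep.all():
            for i in np.flatnonzero(~keep):
                report.removed_samples.append(
                    (cur.samples[i], f"sample call rate {rates[i]:.6g} < {min_sample_call_rate}"))
            if not keep.any():
                raise EmptyResultError("QC removed every sample")
            cur = cur.subset(sample_idx=np.flatnonzero(keep))
            changed = True
        rates = cur.locus_call_rates()
        keep = rates >= min_locus_call_rate
        if not keep.all():
            for j in np.flatnonzero(~keep):
                report.removed_loci.append(
                    (cur.loci[j].id, f"locus call rate {rates[j]:.6g} < {min_locus_call_rate}"))
            if not keep.any():
                raise EmptyResultError("QC removed every locus")
            cur = cur.subset(locus_idx=np.flatnonzero(keep))
            changed = True
        if not changed:
            return cur, report


def compute_allele_frequencies(gm: GenotypeMatrix,
                               population_of: Mapping[str, str] | None = None
                               ) -> FrequencyTable:
    """Per-population allele frequencies by direct allele counting.

    Frequencies use the pairwise-complete convention: each (population,
    locus) denominator is twice the number of non-missing diploid calls
    there. A combination with zero non-missing calls is marked unavailable
    (all-NaN vector) and downstream statistics must reject it.
    """
    if population_of is None:
        population_of = {s: "ALL" for s in gm.samples}
    missing_samples = [s for s in gm.samples if s not in population_of]
    if missing_samples:
        raise ValidationError(f"samples without population label: {missing_samples[:5]}")
    populations = list(dict.fromkeys(population_of[s] for s in gm.samples))
    freqs = np.full((len(populations), gm.n_loci, MAX_ALLELES), np.nan)
    nsamp = np.full((len(populations), gm.n_loci), np.nan)
    for p, pop in enumerate(populations):
        idx = [i for i, s in enumerate(gm.samples) if population_of[s] == pop]
        sub = gm.calls[idx]  # (n_p, L, 2)
        for j, loc in enumerate(gm.loci):
            counts = allele_counts(sub[:, j, :], loc.n_alleles)
            total = counts.sum()
            if total == 0:
                continue  # unavailable
            freqs[p, j, : loc.n_alleles] = counts / total
            freqs[p, j, loc.n_alleles:] = 0.0
            nsamp[p, j] = total // 2
    return FrequencyTable(populations, gm.loci, freqs, nsamp)


@dataclass
class ACRResult:
    """Allele coverage ratios at heterozygous calls.

    ``table`` has columns sample, locus_id, acr; ACR is the less-covered
    allele's depth over the more-covered allele's depth, NaN where both
    depths are zero (those het calls are also listed in ``undefined``).
    """

    table: pd.DataFrame
    undefined: list[tuple[str, str]]

    def locus_means(self) -> pd.Series:
        return self.table.dropna().groupby("locus_id")["acr"].mean()

    def summary(self) -> dict:
        means = self.locus_means()
        return {
            "n_het_calls": int(len(self.table)),
            "n_undefined": len(self.undefined),
            "locus_mean_min": float(means.min()) if len(means) else None,
            "locus_mean_max": float(means.max()) if len(means) else None,
        }


def compute_acr(dt: DepthTable, gm: GenotypeMatrix) -> ACRResult:
    """Coverage balance at heterozygous calls: min(depth)/max(depth) in [0, 1].

    Homozygous and missing calls are excluded; a het call with zero depth on
    both alleles is reported as undefined. Symmetric in the two alleles.
    """
    if dt.samples != gm.samples or dt.loci != gm.loci:
        raise ValidationError("depth table is not aligned with the genotype matrix")
    rows = []
    undefined = []
    het = gm.het_mask()
    for i, j in np.argwhere(het):
        a, b = gm.calls[i, j]
        da, db = int(dt.depths[i, j, a]), int(dt.depths[i, j, b])
        if da < 0 or db < 0:
            raise ValidationError(
                f"no depth recorded for het call {gm.samples[i]} @ {gm.loci[j].id}")
        if da == 0 and db == 0:
            undefined.append((gm.samples[i], gm.loci[j].id))
            rows.append((gm.samples[i], gm.loci[j].id, np.nan))
        else:
            rows.append((gm.samples[i], gm.loci[j].id, min(da, db) / max(da, db)))
    return ACRResult(pd.DataFrame(rows, columns=["sample", "locus_id", "acr"]), undefined)


def minor_allele_frequency(freqs: np.ndarray) -> float:
    """MAF as 1 - max allele frequency (handles tri-allelic loci)."""
    return float(1.0 - np.nanmax(freqs))


def maf_ld_prune(gm: GenotypeMatrix, min_maf: float = 0.05, r2_threshold: float = 0.2,
                 window: int = 50, step: int = 5) -> list[str]:
    """MAF filter followed by windowed LD pruning; returns retained locus ids.

    Loci must have MAF strictly above ``min_maf``. Pruning slides a
    ``window``-locus window by ``step``, estimates r^2 by EM within the
    window, and greedily drops the later locus of any pair with
    r^2 > ``r2_threshold``; deterministic given input order. Tri-allelic
    loci are collapsed to major-allele-vs-rest for the r^2 computation.
    """
    import warnings

    from .forensic import ld_r2

    if not 0.0 <= min_maf <= 0.5:
        raise ValidationError(f"min_maf must be in [0, 0.5], got {min_maf}")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValidationError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    keep: list[int] = []
    for j, loc in enumerate(gm.loci):
        counts = allele_counts(gm.column(j), loc.n_alleles)
        if counts.sum() == 0:
            continue
        if minor_allele_frequency(counts / counts.sum()) > min_maf:
            keep.append(j)
    # collapse to 0/1 columns (major allele vs rest) once, for r^2
    def collapsed(j: int) -> np.ndarray:
        col = gm.column(j).copy()
        counts = allele_counts(col, gm.loci[j].n_alleles)
        major = int(np.argmax(counts))
        out = np.where(col == MISSING, MISSING, np.where(col == major, 0, 1))
        return out.astype(np.int8)

    cols = {j: collapsed(j) for j in keep}
    removed: set[int] = set()
    start = 0
    while True:
        win = [j for j in keep[start:start + window] if j not in removed]
        for x in range(len(win)):
            if win[x] in removed:
                continue
            for y in range(x + 1, len(win)):
                if win[y] in removed:
                    continue
                res = ld_r2_collapsed(cols[win[x]], cols[win[y]], r2_threshold)
                if res is not None and res > r2_threshold:
                    removed.add(win[y])
        if start + window >= len(keep):
            break
        start += step
    retained = [gm.loci[j].id for j in keep if j not in removed]
    if not retained:
        warnings.warn("MAF/LD pruning removed every locus", stacklevel=2)
    return retained


def ld_r2_collapsed(col1: np.ndarray, col2: np.ndarray, threshold: float) -> float | None:
    """r^2 between two pre-collapsed diallelic 0/1 columns; None if degenerate."""
    from .forensic import _em_r2

    ok = (col1[:, 0] != MISSING) & (col2[:, 0] != MISSING)
    if ok.sum() < 2:
        return None
    g1 = col1[ok].sum(axis=1)
    g2 = col2[ok].sum(axis=1)
    return _em_r2(g1, g2)
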