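"""Readers and writers for the package's on-disk formats.

Supported formats:

* VCF v4.2 with GT (and optionally AD) — read through cyvcf2/htslib, written
  by a minimal text writer sufficient for round-tripping panel genotypes.
* Genotype TSV — one row per sample, one column per locus, calls as "A/C",
  missing as "./."; locus metadata in ``##locus`` header lines.
* Frequency TSV — long format, one row per (population, locus, allele) with
  columns locus_id, chrom, pos, population, allele, frequency, n_samples.
* Depth TSV — one row per (sample, locus, allele) with a read depth.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParseError, UnsupportedLocusError, ValidationError
from .loci import (MAX_ALLELES, MISSING, DepthTable, FrequencyTable,
                   GenotypeMatrix, Locus)

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, return_depths: bool = False):
    """Read a VCF into a :class:`GenotypeMatrix`.

    Phase separators are ignored (all calls treated as unordered), missing
    GT becomes MISSING. Sites with more than three alleles are rejected.
    With ``return_depths=True`` also builds a :class:`DepthTable` from the
    AD FORMAT field (depths of -1 where AD is absent).
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    try:
        for var in vcf:
            alleles = (var.REF, *var.ALT)
            if len(alleles) > MAX_ALLELES:
                raise UnsupportedLocusError(
                    f"{path}: site {var.CHROM}:{var.POS} has {len(alleles)} alleles; "
                    "only diallelic/tri-allelic sites are supported"
                )
            lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            loci.append(Locus(lid, var.CHROM, var.POS, tuple(alleles)))
            col = np.array([gt[:2] for gt in var.genotypes], dtype=np.int8)
            col[(col == -1).any(axis=1)] = MISSING
            cols.append(col)
            if return_depths:
                ad = var.format("AD")
                if ad is None:
                    depth_cols.append(np.full((len(samples), MAX_ALLELES), -1, np.int32))
                else:
                    d = np.full((len(samples), MAX_ALLELES), -1, np.int32)
                    ad = np.asarray(ad, dtype=np.int64)
                    k = min(ad.shape[1], len(alleles))
                    d[:, :k] = np.where(ad[:, :k] < 0, -1, ad[:, :k])
                    depth_cols.append(d)
    except UnsupportedLocusError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF record near locus {len(loci) + 1}: {exc}") from exc
    if not loci:
        raise ParseError(f"{path}: VCF contains no records")
    gm = GenotypeMatrix(samples, loci, np.stack(cols, axis=1))
    if return_depths:
        dt = DepthTable(samples, loci, np.stack(depth_cols, axis=1))
        return gm, dt
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) readable by htslib."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(loc.chrom for loc in gm.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, loc in enumerate(gm.loci):
            alt = ",".join(loc.alleles[1:])
            gts = []
            for i in range(gm.n_samples):
                a, b = gm.calls[i, j]
                gts.append("./." if a == MISSING else f"{min(a, b)}/{max(a, b)}")
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.alleles[0]}\t{alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Genotype TSV dialect
# ---------------------------------------------------------------------------

def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for loc in gm.loci:
            fh.write(f"##locus\t{loc.id}\t{loc.chrom}\t{loc.pos}\t{','.join(loc.alleles)}\n")
        fh.write("sample\t" + "\t".join(gm.locus_ids) + "\n")
        for i, sample in enumerate(gm.samples):
            cells = []
            for j, loc in enumerate(gm.loci):
                a, b = gm.calls[i, j]
                cells.append("./." if a == MISSING
                             else f"{loc.alleles[min(a, b)]}/{loc.alleles[max(a, b)]}")
            fh.write(sample + "\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    loci: list[Locus] = []
    samples: list[str] = []
    rows: list[list[str]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##locus\t"):
                try:
                    _, lid, chrom, pos, alleles = line.split("\t")
                    loci.append(Locus(lid, chrom, int(pos), tuple(alleles.split(","))))
                except (ValueError, ValidationError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad ##locus line: {exc}") from exc
            elif header is None:
                header = line.split("\t")
            else:
                fields = line.split("\t")
                samples.append(fields[0])
                rows.append(fields[1:])
    if header is None or not loci:
        raise ParseError(f"{path}: missing header or ##locus metadata")
    if header[1:] != [loc.id for loc in loci]:
        raise ParseError(f"{path}: column order does not match ##locus lines")
    calls = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        if len(row) != len(loci):
            raise ParseError(f"{path}: sample {samples[i]} has {len(row)} calls, "
                             f"expected {len(loci)}")
        for j, cell in enumerate(row):
            if cell == "./.":
                continue
            try:
                a, b = cell.split("/")
                calls[i, j] = sorted((loci[j].alleles.index(a), loci[j].alleles.index(b)))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: sample {samples[i]}, locus {loci[j].id}: bad call {cell!r}"
                ) from exc
    return GenotypeMatrix(samples, loci, calls)


# ---------------------------------------------------------------------------
# Frequency TSV (long format)
# ---------------------------------------------------------------------------

FREQ_COLUMNS = ["locus_id", "chrom", "pos", "population", "allele", "frequency", "n_samples"]
_READ_SUM_TOL = 1e-6


def write_frequency_table(ft: FrequencyTable, path: str | Path) -> None:
    path = Path(path)
    avail = ft.available()
    with path.open("w") as fh:
        fh.write("\t".join(FREQ_COLUMNS) + "\n")
        for p, pop in enumerate(ft.populations):
            for l, loc in enumerate(ft.loci):
                if not avail[p, l]:
                    continue
                ns = ft.n_samples[p, l]
                ns_str = "" if np.isnan(ns) else str(int(ns))
                for j, allele in enumerate(loc.alleles):
                    fh.write(f"{loc.id}\t{loc.chrom}\t{loc.pos}\t{pop}\t{allele}\t"
                             f"{float(ft.freqs[p, l, j])!r}\t{ns_str}\n")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read the long-format frequency TSV.

    Populations and loci keep file order; allele order per locus follows
    first appearance. A per-(population, locus) vector not summing to 1
    within 1e-6 is a validation error naming the locus.
    """
    path = Path(path)
    pops: dict[str, None] = {}
    loci_order: dict[str, Locus] = {}
    allele_order: dict[str, list[str]] = {}
    records: list[tuple[str, str, str, float, float]] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [c for c in FREQ_COLUMNS[:6] if c not in reader.fieldnames]:
            raise ParseError(f"{path}: expected columns {FREQ_COLUMNS}")
        for lineno, row in enumerate(reader, 2):
            try:
                lid, chrom, pos = row["locus_id"], row["chrom"], int(row["pos"])
                pop, allele = row["population"], row["allele"]
                freq = float(row["frequency"])
                ns = float(row["n_samples"]) if row.get("n_samples") else np.nan
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            pops.setdefault(pop)
            if lid not in allele_order:
                allele_order[lid] = []
                loci_order[lid] = (lid, chrom, pos)  # type: ignore[assignment]
            if allele not in allele_order[lid]:
                allele_order[lid].append(allele)
            records.append((lid, pop, allele, freq, ns))
    loci = [Locus(lid, chrom, pos, tuple(allele_order[lid]))
            for lid, (_, chrom, pos) in ((k, v) for k, v in loci_order.items())]
    populations = list(pops)
    lidx = {loc.id: j for j, loc in enumerate(loci)}
    pidx = {p: i for i, p in enumerate(populations)}
    freqs = np.full((len(populations), len(loci), MAX_ALLELES), np.nan)
    nsamp = np.full((len(populations), len(loci)), np.nan)
    for lid, pop, allele, freq, ns in records:
        j = lidx[lid]
        a = loci[j].alleles.index(allele)
        if np.isnan(freqs[pidx[pop], j, a]):
            freqs[pidx[pop], j, a] = 0.0
        freqs[pidx[pop], j, a] = freq
        nsamp[pidx[pop], j] = ns
    # fill unstated alleles of present vectors with 0, then validate sums
    for p in range(len(populations)):
        for j, loc in enumerate(loci):
            vec = freqs[p, j, : loc.n_alleles]
            if np.isnan(vec).all():
                continue
            vec = np.nan_to_num(vec)
            if abs(vec.sum() - 1.0) > _READ_SUM_TOL:
                raise ValidationError(
                    f"{path}: locus {loc.id}, population {populations[p]}: "
                    f"frequencies sum to {vec.sum():.8f}, not 1"
                )
            vec = vec / vec.sum()  # remove <=1e-6 rounding before strict validation
            freqs[p, j, : loc.n_alleles] = vec
            freqs[p, j, loc.n_alleles:] = 0.0
    return FrequencyTable(populations, loci, freqs, nsamp)


# ---------------------------------------------------------------------------
# Depth TSV
# ---------------------------------------------------------------------------

def write_depth_table(dt: DepthTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tlocus_id\tallele\tdepth\n")
        for i, sample in enumerate(dt.samples):
            for j, loc in enumerate(dt.loci):
                for a, allele in enumerate(loc.alleles):
                    d = dt.depths[i, j, a]
                    if d >= 0:
                        fh.write(f"{sample}\t{loc.id}\t{allele}\t{d}\n")


def read_depth_table(path: str | Path, gm: GenotypeMatrix) -> DepthTable:
    """Read a depth TSV aligned against an existing genotype matrix."""
    path = Path(path)
    depths = np.full((gm.n_samples, gm.n_loci, MAX_ALLELES), -1, np.int32)
    sidx = {s: i for i, s in enumerate(gm.samples)}
    lidx = {loc.id: j for j, loc in enumerate(gm.loci)}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                i = sidx[row["sample"]]
                j = lidx[row["locus_id"]]
                a = gm.loci[j].alleles.index(row["allele"])
                d = int(row["depth"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad depth row: {exc}") from exc
            if d < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth")
            depths[i, j, a] = d
    return DepthTable(gm.samples, gm.loci, depths)
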