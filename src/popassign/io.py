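"""Readers and writers for PLINK text (ped/map), EIGENSTRAT and HapMap.

All readers accept a path or an open text stream; writers likewise.  The
PLINK dialect is whitespace-delimited text with nucleotide letters (binary
bed/bim/fam is out of scope).  EIGENSTRAT uses the usual three files: geno
digits (copies of the counted allele, 9 = missing, one marker per line),
snp metadata and an ind file whose third column carries the population.
HapMap is export-only.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable

import numpy as np

from .data import (
    MISSING,
    VALID_ALLELES,
    FormatError,
    GenotypeDataError,
    GenotypeDataset,
    Marker,
    Sample,
)

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_eigenstrat",
    "write_eigenstrat",
    "write_hapmap",
    "write_curation_report",
]


def _lines(source: str | Path | IO[str]) -> list[str]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    return [ln for ln in text.splitlines() if ln.strip()]


def _opened(target: str | Path | IO[str]):
    """Return (stream, needs_close)."""
    if isinstance(target, (str, Path)):
        return open(target, "w"), True
    return target, False


# ---------------------------------------------------------------------------
# PLINK text ped/map
# ---------------------------------------------------------------------------

def read_ped_map(
    ped_source: str | Path | IO[str], map_source: str | Path | IO[str]
) -> GenotypeDataset:
    """Parse whitespace-delimited ped/map text into a dataset.

    The ped family column becomes the sample's population label; ``0``
    alleles are parsed as missing (a half-called genotype is treated as
    fully missing).  The counted allele of each marker is the first
    non-missing allele letter encountered in ped row order.
    """
    map_lines = _lines(map_source)
    markers_meta: list[tuple[str, str, int]] = []
    for i, ln in enumerate(map_lines, start=1):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"map line {i}: expected 4 columns, got {len(parts)}")
        chrom, mid, _cm, pos = parts[0], parts[1], parts[2], parts[3]
        markers_meta.append((mid, chrom, int(pos)))
    n_markers = len(markers_meta)

    ped_lines = _lines(ped_source)
    samples: list[Sample] = []
    rows: list[list[str]] = []
    expected = 6 + 2 * n_markers
    for i, ln in enumerate(ped_lines, start=1):
        parts = ln.split()
        if len(parts) != expected:
            raise FormatError(
                f"ped line {i}: expected {expected} fields "
                f"(6 + 2 x {n_markers} markers), got {len(parts)}"
            )
        fam, iid = parts[0], parts[1]
        samples.append(Sample(id=iid, population=fam))
        rows.append(parts[6:])

    allele_arr = np.array(rows, dtype="<U8") if rows else \
        np.empty((0, 2 * n_markers), dtype="<U8")
    bad = ~np.isin(allele_arr, list(VALID_ALLELES) + ["0"])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"ped line {i + 1}: allele token {allele_arr[i, j]!r} "
            "not in {A,C,G,T,0}"
        )
    pairs = allele_arr.reshape(len(rows), n_markers, 2) if rows else \
        np.empty((0, n_markers, 2), dtype="<U8")

    markers: list[Marker] = []
    genotypes = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    for j, (mid, chrom, pos) in enumerate(markers_meta):
        col = pairs[:, j, :] if rows else np.empty((0, 2), dtype="<U8")
        flat = col.ravel()
        nonmiss = flat[flat != "0"]
        letters = list(dict.fromkeys(nonmiss))  # first-observed order
        if len(letters) > 2:
            raise GenotypeDataError(
                f"marker {mid}: more than 2 distinct alleles observed "
                f"({sorted(set(nonmiss))})"
            )
        counted = letters[0] if letters else "0"
        other = letters[1] if len(letters) > 1 else "0"
        markers.append(Marker(mid, chrom, pos, (counted, other)))
        if rows:
            miss = (col == "0").any(axis=1)
            d = (col == counted).sum(axis=1).astype(np.int8)
            genotypes[:, j] = np.where(miss, MISSING, d)
    return GenotypeDataset(samples, markers, genotypes)


def write_ped_map(
    dataset: GenotypeDataset,
    ped_target: str | Path | IO[str],
    map_target: str | Path | IO[str],
) -> None:
    """Write a dataset as whitespace-delimited ped/map text."""
    stream, close = _opened(map_target)
    try:
        for m in dataset.markers:
            stream.write(f"{m.chromosome}\t{m.id}\t0\t{m.position}\n")
    finally:
        if close:
            stream.close()

    letters = _letter_matrix(dataset)
    stream, close = _opened(ped_target)
    try:
        for i, s in enumerate(dataset.samples):
            lead = [s.population, s.id, "0", "0", "0", "-9"]
            stream.write(" ".join(lead + list(letters[i])) + "\n")
    finally:
        if close:
            stream.close()


def _letter_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """(n_samples, 2 * n_markers) array of allele letters ('0' = missing)."""
    n, m = dataset.shape
    out = np.full((n, m, 2), "0", dtype="<U1")
    g = dataset.genotypes
    for j, mk in enumerate(dataset.markers):
        a, b = mk.alleles
        col = g[:, j]
        out[col == 2, j, :] = [a, a]
        out[col == 1, j, :] = [a, b]
        out[col == 0, j, :] = [b, b]
    return out.reshape(n, 2 * m)


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def write_eigenstrat(
    dataset: GenotypeDataset,
    geno_target: str | Path | IO[str],
    snp_target: str | Path | IO[str],
    ind_target: str | Path | IO[str],
) -> None:
    """Write geno/snp/ind files.

    Geno coding: copies of the counted allele (2 = counted homozygote,
    1 = heterozygote, 0 = other homozygote, 9 = missing), one marker per
    line, one digit per sample.
    """
    for j, m in enumerate(dataset.markers):
        col = dataset.genotypes[:, j]
        if m.counted_allele == "0" and (col != MISSING).any():
            raise GenotypeDataError(
                f"marker {m.id}: non-missing calls but undefined alleles"
            )
    digits = np.where(dataset.genotypes == MISSING, 9,
                      dataset.genotypes).astype(np.int8)
    stream, close = _opened(geno_target)
    try:
        for j in range(dataset.n_markers):
            stream.write("".join(map(str, digits[:, j])) + "\n")
    finally:
        if close:
            stream.close()
    stream, close = _opened(snp_target)
    try:
        for m in dataset.markers:
            stream.write(
                f"{m.id}\t{m.chromosome}\t0.0\t{m.position}"
                f"\t{m.counted_allele}\t{m.other_allele}\n"
            )
    finally:
        if close:
            stream.close()
    stream, close = _opened(ind_target)
    try:
        for s in dataset.samples:
            stream.write(f"{s.id}\tU\t{s.population}\n")
    finally:
        if close:
            stream.close()


def read_eigenstrat(
    geno_source: str | Path | IO[str],
    snp_source: str | Path | IO[str],
    ind_source: str | Path | IO[str],
) -> GenotypeDataset:
    """Parse EIGENSTRAT geno/snp/ind files into a dataset."""
    snp_lines = _lines(snp_source)
    markers: list[Marker] = []
    for i, ln in enumerate(snp_lines, start=1):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"snp line {i}: expected >= 4 columns")
        mid, chrom, pos = parts[0], parts[1], int(parts[3])
        a1 = parts[4] if len(parts) > 4 else "0"
        a2 = parts[5] if len(parts) > 5 else "0"
        markers.append(Marker(mid, chrom, pos, (a1, a2)))

    ind_lines = _lines(ind_source)
    samples = []
    for i, ln in enumerate(ind_lines, start=1):
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"ind line {i}: expected 3 columns (id sex population)")
        samples.append(Sample(id=parts[0], population=parts[2]))

    geno_lines = _lines(geno_source)
    if len(geno_lines) != len(markers):
        raise FormatError(
            f"geno file has {len(geno_lines)} lines but snp file lists "
            f"{len(markers)} markers"
        )
    genotypes = np.full((len(samples), len(markers)), MISSING, dtype=np.int8)
    for j, ln in enumerate(geno_lines):
        row = ln.strip()
        if len(row) != len(samples):
            raise FormatError(
                f"geno line {j + 1}: {len(row)} digits for {len(samples)} samples"
            )
        vals = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
        if not np.isin(vals, (0, 1, 2, 9)).all():
            raise FormatError(f"geno line {j + 1}: digits must be 0/1/2/9")
        genotypes[:, j] = np.where(vals == 9, MISSING, vals)
    return GenotypeDataset(samples, markers, genotypes)


# ---------------------------------------------------------------------------
# HapMap (export only)
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def write_hapmap(dataset: GenotypeDataset, target: str | Path | IO[str]) -> None:
    """Write the tab-delimited HapMap genotype table (write-only format)."""
    stream, close = _opened(target)
    try:
        stream.write("\t".join(_HAPMAP_META + dataset.sample_ids) + "\n")
        letters = _letter_matrix(dataset).reshape(dataset.n_samples,
                                                  dataset.n_markers, 2)
        for j, m in enumerate(dataset.markers):
            pair = f"{m.counted_allele}/{m.other_allele}"
            meta = [m.id, pair, str(m.chromosome), str(m.position), "+",
                    "NA", "NA", "NA", "NA", "NA", "NA"]
            calls = []
            for i in range(dataset.n_samples):
                a, b = letters[i, j]
                calls.append("NN" if a == "0" else a + b)
            stream.write("\t".join(meta + calls) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Curation report
# ---------------------------------------------------------------------------

def write_curation_report(groups: Iterable, target: str | Path | IO[str]) -> None:
    """Write positional-duplicate groups as TSV."""
    stream, close = _opened(target)
    try:
        stream.write("chromosome\tposition\tmembers\tkept\tconcordant\n")
        for g in groups:
            stream.write(
                f"{g.chromosome}\t{g.position}\t{','.join(g.member_ids)}\t"
                f"{g.kept_id or '-'}\t{'yes' if g.concordant else 'no'}\n"
            )
    finally:
        if close:
            stream.close()
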