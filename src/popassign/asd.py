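"""Allele sharing distance (ASD) between individuals.

For two diploid genotypes at one biallelic locus, the proportion of alleles
alike in state is the size of the multiset intersection of the two allele
pairs divided by two: identical homozygotes share 1, a homozygote and a
heterozygote share 0.5, two heterozygotes share 1, opposite homozygotes
share 0.  In dosage terms this is ``1 - |d1 - d2| / 2``.  ASD between two
individuals is one minus the mean proportion over all loci genotyped in
both (pairwise-complete), so it lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset

__all__ = [
    "AsdMatrix",
    "asd_pair",
    "asd_query_vs_reference",
    "population_asd_summary",
    "write_asd_outputs",
]


class ZeroOverlapError(ValueError):
    """No locus genotyped in both members of a pair."""


def asd_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """ASD between two dosage vectors over loci non-missing in both."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    both = (g1 != MISSING) & (g2 != MISSING)
    if not both.any():
        raise ZeroOverlapError("no overlapping genotyped loci between the pair")
    return float(np.abs(g1[both] - g2[both]).mean() / 2.0)


@dataclass
class AsdMatrix:
    """Query x reference-individual distances with per-pair overlap counts.

    Cells with zero overlapping genotyped loci hold NaN (overlap 0) so they
    can never be mistaken for a real distance.
    """

    query_ids: list[str]
    reference_ids: list[str]
    reference_populations: list[str]
    values: np.ndarray   # (n_query, n_reference), in [0, 1] or NaN
    overlap: np.ndarray  # (n_query, n_reference) int

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.query_ids):
            for j, r in enumerate(self.reference_ids):
                rows.append((q, r, self.reference_populations[j],
                             self.values[i, j], int(self.overlap[i, j])))
        return pd.DataFrame(rows, columns=["query", "reference",
                                           "reference_population", "asd",
                                           "n_overlap"])


def asd_query_vs_reference(
    dataset: GenotypeDataset,
    query_ids: Sequence[str],
    reference_ids: Sequence[str],
) -> AsdMatrix:
    """Pairwise-complete ASD between query and reference individuals.

    Both id lists must name samples of ``dataset`` (typically a merged
    dataset over shared markers).
    """
    index = {s.id: i for i, s in enumerate(dataset.samples)}
    qi = [index[q] for q in query_ids]
    ri = [index[r] for r in reference_ids]
    gq = dataset.genotypes[qi, :]
    gr = dataset.genotypes[ri, :]
    mq = (gq != MISSING)
    mr = (gr != MISSING)

    # Decompose |d1 - d2| into dosage-indicator matrix products so the whole
    # matrix is a handful of BLAS calls instead of an n_q x n_r Python loop.
    overlap = mq.astype(np.float64) @ mr.astype(np.float64).T
    diff_sum = np.zeros_like(overlap)
    q_ind = [( (gq == d) & mq ).astype(np.float64) for d in (0, 1, 2)]
    r_ind = [( (gr == d) & mr ).astype(np.float64) for d in (0, 1, 2)]
    for d1 in (0, 1, 2):
        for d2 in (0, 1, 2):
            w = abs(d1 - d2)
            if w:
                diff_sum += w * (q_ind[d1] @ r_ind[d2].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(overlap > 0, diff_sum / (2.0 * overlap), np.nan)
    pops = [dataset.samples[i].population for i in ri]
    return AsdMatrix(list(query_ids), list(reference_ids), pops,
                     values, overlap.astype(np.int64))


def population_asd_summary(asd: AsdMatrix, top_n: int = 5) -> pd.DataFrame:
    """Top-N genetically closest reference populations per query.

    Populations are ranked by ascending mean ASD (ties broken by label
    order); each row carries the mean, minimum and maximum ASD within the
    population and its reference-individual count.
    """
    pops = np.asarray(asd.reference_populations)
    labels = sorted(set(asd.reference_populations))
    rows = []
    for i, q in enumerate(asd.query_ids):
        stats = []
        for lab in labels:
            cols = np.flatnonzero(pops == lab)
            vals = asd.values[i, cols]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            stats.append((float(vals.mean()), lab, float(vals.min()),
                          float(vals.max()), int(vals.size)))
        stats.sort()  # ascending mean, then label
        for rank, (mean, lab, vmin, vmax, size) in enumerate(stats[:top_n], 1):
            rows.append((q, rank, lab, mean, vmin, vmax, size))
    return pd.DataFrame(rows, columns=["query", "rank", "population",
                                       "mean_asd", "min_asd", "max_asd",
                                       "n_individuals"])


def write_asd_outputs(
    asd: AsdMatrix,
    results_target: str | Path | IO[str],
    summary_target: str | Path | IO[str],
    top_n: int = 5,
) -> None:
    """Write asd_results.tsv (long-format matrix) and asd_summary.tsv."""
    asd.to_long_frame().to_csv(results_target, sep="\t", index=False)
    population_asd_summary(asd, top_n).to_csv(summary_target, sep="\t",
                                              index=False)
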