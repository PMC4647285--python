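"""Quality-filtering cascade for genotype datasets.

The cascade mirrors common SNP-panel curation practice: call-rate filters
on individuals and markers (in either order), an exact Hardy-Weinberg
equilibrium test to discard outlying markers, and a minor-allele-frequency
filter for poorly informative markers.  Each stage records what it removed
in a :class:`SelectionSummary` that serialises to a ``selection.txt`` TSV.

Call-rate comparisons are non-strict ("minimum call rate": keep when the
rate is >= the threshold); HWE and MAF removals are strict (remove when
P < threshold, MAF < threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .data import GenotypeDataset

__all__ = [
    "QcConfig",
    "Stage",
    "SelectionSummary",
    "hwe_exact_test",
    "call_rate_filter",
    "hwe_filter",
    "maf_filter",
    "run_qc",
    "write_selection_summary",
]


@dataclass
class QcConfig:
    """Thresholds and switches for the filtering cascade.

    Defaults: individual call rate 0.95, marker call rate 0.75, HWE exact
    test at P < 0.001, MAF < 0.01; individuals are filtered before markers
    unless ``reverse_call_rate_order`` is set.
    """

    min_individual_call_rate: float = 0.95
    min_marker_call_rate: float = 0.75
    reverse_call_rate_order: bool = False
    hwe_p_threshold: float = 0.001
    min_maf: float = 0.01
    enable_call_rate: bool = True
    enable_hwe: bool = True
    enable_maf: bool = True
    #: test HWE within each population and remove on the minimum p-value,
    #: instead of pooling genotype counts over all selected individuals
    hwe_per_population: bool = False

    def __post_init__(self) -> None:
        for name in ("min_individual_call_rate", "min_marker_call_rate",
                     "hwe_p_threshold", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class Stage:
    name: str
    n_samples_in: int
    n_samples_out: int
    n_markers_in: int
    n_markers_out: int
    removed_samples: list[str] = field(default_factory=list)
    removed_markers: list[str] = field(default_factory=list)


@dataclass
class SelectionSummary:
    stages: list[Stage] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def extend(self, other: "SelectionSummary") -> None:
        self.stages.extend(other.stages)
        self.warnings.extend(other.warnings)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "samples_before": s.n_samples_in,
                    "samples_after": s.n_samples_out,
                    "markers_before": s.n_markers_in,
                    "markers_after": s.n_markers_out,
                    "removed_samples": ",".join(s.removed_samples) or "-",
                    "removed_markers": ",".join(s.removed_markers) or "-",
                }
                for s in self.stages
            ]
        )


def write_selection_summary(
    summary: SelectionSummary, target: str | Path | IO[str]
) -> None:
    """Write the stage-by-stage selection summary (selection.txt layout)."""
    frame = summary.to_frame()
    if isinstance(target, (str, Path)):
        frame.to_csv(target, sep="\t", index=False)
    else:
        frame.to_csv(target, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _het_probabilities(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Enumerates every heterozygote count attainable with ``n`` diploids and
    ``n_a`` copies of the counted allele (the parity of the count is fixed
    by ``n_a``), building the probabilities through the ratio recurrence

        P(h+2) / P(h) = 4 * nAA(h) * nBB(h) / ((h+2) * (h+1))

    accumulated in log space and normalised to sum to one.
    """
    n_b = 2 * n - n_a
    h_max = min(n_a, n_b)
    parity = n_a % 2
    hs = np.arange(parity, h_max + 1, 2)
    if hs.size == 0:  # n_a == 0 or n_b == 0 with odd parity cannot occur
        hs = np.array([0])
    if hs.size == 1:
        return hs, np.ones(1)
    h = hs[:-1].astype(float)
    n_aa = (n_a - h) / 2.0
    n_bb = (n_b - h) / 2.0
    log_ratio = (np.log(4.0) + np.log(n_aa) + np.log(n_bb)
                 - np.log(h + 2.0) - np.log(h + 1.0))
    logw = np.concatenate([[0.0], np.cumsum(log_ratio)])
    logw -= logw.max()
    w = np.exp(logw)
    return hs, w / w.sum()


def hwe_exact_test(n_hom_counted: int, n_het: int, n_hom_other: int) -> float:
    """Two-sided exact Hardy-Weinberg test at a biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration no more probable than the observed one.
    Returns a p-value in (0, 1].
    """
    if min(n_hom_counted, n_het, n_hom_other) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_counted + n_het + n_hom_other
    if n == 0:
        raise ValueError("exact HWE test undefined with zero genotyped individuals")
    n_a = 2 * n_hom_counted + n_het
    hs, probs = _het_probabilities(n, n_a)
    p_obs = probs[hs == n_het][0]
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _sample_stage(dataset: GenotypeDataset, threshold: float) -> tuple:
    rates = dataset.sample_call_rates()
    keep = np.flatnonzero(rates >= threshold)
    removed = [dataset.samples[i].id for i in np.flatnonzero(rates < threshold)]
    return dataset.take(sample_indices=keep), removed


def _marker_stage(dataset: GenotypeDataset, threshold: float) -> tuple:
    rates = dataset.marker_call_rates()
    keep = np.flatnonzero(rates >= threshold)
    removed = [dataset.markers[j].id for j in np.flatnonzero(rates < threshold)]
    return dataset.take(marker_indices=keep), removed


def call_rate_filter(
    dataset: GenotypeDataset, config: QcConfig | None = None
) -> tuple[GenotypeDataset, SelectionSummary]:
    """Two-stage call-rate filter.

    Default order filters individuals first (call rate over all current
    markers), then markers (call rate over the surviving individuals);
    ``reverse_call_rate_order`` swaps the stages.  The second stage is
    always computed on the first stage's survivors.
    """
    config = config or QcConfig()
    summary = SelectionSummary()
    current = dataset
    order = ("marker", "individual") if config.reverse_call_rate_order \
        else ("individual", "marker")
    for kind in order:
        n_s, n_m = current.shape
        if kind == "individual":
            nxt, removed = _sample_stage(current, config.min_individual_call_rate)
            summary.stages.append(Stage("individual_call_rate", n_s,
                                        nxt.n_samples, n_m, nxt.n_markers,
                                        removed_samples=removed))
        else:
            nxt, removed = _marker_stage(current, config.min_marker_call_rate)
            summary.stages.append(Stage("marker_call_rate", n_s, nxt.n_samples,
                                        n_m, nxt.n_markers,
                                        removed_markers=removed))
        current = nxt
    if current.n_samples == 0:
        summary.warnings.append("call-rate filtering removed every sample")
    if current.n_markers == 0:
        summary.warnings.append("call-rate filtering removed every marker")
    return current, summary


def _marker_hwe_pvalues(dataset: GenotypeDataset, per_population: bool) -> np.ndarray:
    g = dataset.genotypes
    groups: list[np.ndarray]
    if per_population:
        by_pop: dict[str, list[int]] = {}
        for i, s in enumerate(dataset.samples):
            by_pop.setdefault(s.population, []).append(i)
        groups = [np.asarray(v) for v in by_pop.values()]
    else:
        groups = [np.arange(dataset.n_samples)]
    pvals = np.ones(dataset.n_markers)
    for j in range(dataset.n_markers):
        p_min = 1.0
        for rows in groups:
            col = g[rows, j]
            n2 = int((col == 2).sum())
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            if n2 + n1 + n0 == 0:
                continue
            p_min = min(p_min, hwe_exact_test(n2, n1, n0))
        pvals[j] = p_min
    return pvals


def hwe_filter(
    dataset: GenotypeDataset, config: QcConfig | None = None
) -> tuple[GenotypeDataset, SelectionSummary]:
    """Remove markers whose exact HWE p-value falls below the threshold.

    Genotype counts are pooled over all currently selected individuals by
    default (``hwe_per_population`` tests within populations instead).
    """
    config = config or QcConfig()
    pvals = _marker_hwe_pvalues(dataset, config.hwe_per_population)
    keep = np.flatnonzero(~(pvals < config.hwe_p_threshold))
    removed = [dataset.markers[j].id
               for j in np.flatnonzero(pvals < config.hwe_p_threshold)]
    out = dataset.take(marker_indices=keep)
    summary = SelectionSummary([Stage("hwe", dataset.n_samples, out.n_samples,
                                      dataset.n_markers, out.n_markers,
                                      removed_markers=removed)])
    return out, summary


def maf_filter(
    dataset: GenotypeDataset, config: QcConfig | None = None
) -> tuple[GenotypeDataset, SelectionSummary]:
    """Remove markers with minor allele frequency below the threshold.

    The MAF is computed over all non-missing calls pooled across
    populations; markers with no calls count as MAF 0.
    """
    config = config or QcConfig()
    freq = dataset.allele_frequencies()
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(~(maf < config.min_maf))
    removed = [dataset.markers[j].id
               for j in np.flatnonzero(maf < config.min_maf)]
    out = dataset.take(marker_indices=keep)
    summary = SelectionSummary([Stage("maf", dataset.n_samples, out.n_samples,
                                      dataset.n_markers, out.n_markers,
                                      removed_markers=removed)])
    return out, summary


def run_qc(
    dataset: GenotypeDataset, config: QcConfig | None = None
) -> tuple[GenotypeDataset, SelectionSummary]:
    """Apply the enabled filters in cascade order: call rates, HWE, MAF."""
    config = config or QcConfig()
    summary = SelectionSummary()
    current = dataset
    if config.enable_call_rate:
        current, s = call_rate_filter(current, config)
        summary.extend(s)
    if config.enable_hwe and current.n_samples > 0:
        current, s = hwe_filter(current, config)
        summary.extend(s)
    if config.enable_maf and current.n_samples > 0:
        current, s = maf_filter(current, config)
        summary.extend(s)
    return current, summary
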