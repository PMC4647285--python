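"""Threshold-based population assignment and its evaluation.

An individual is assigned to the population with the highest estimated
ancestry proportion if and only if that maximum strictly exceeds the
ancestry threshold t (ties broken by population label order and flagged).
Over a set of queries with known origins, the assignment rate is the
fraction of queries assigned, and the misassignment rate is the fraction
of *assigned* queries whose call differs from their population of origin
(undefined — reported as NaN, never 0 — when nothing was assigned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import AncestryProportions, EmConfig, build_reference_panel, \
    supervised_em
from .data import GenotypeDataset

__all__ = [
    "AssignmentOutcome",
    "assign",
    "rates",
    "rate_curve",
    "self_assignment_experiment",
    "default_thresholds",
]

UNASSIGNED = None


@dataclass
class AssignmentOutcome:
    sample_id: str
    population: str | None  # None = unassigned
    ancestry: float          # the max q supporting (or failing) the call
    threshold: float
    tied: bool = False


def default_thresholds(n_points: int = 101) -> np.ndarray:
    """Evenly spaced ancestry thresholds spanning [0, 1]."""
    return np.linspace(0.0, 1.0, n_points)


def assign(result: AncestryProportions, threshold: float) -> list[AssignmentOutcome]:
    """Assign each query to its argmax population iff max q > threshold.

    The comparison is strict: a query whose maximum ancestry equals the
    threshold exactly stays unassigned.  Exact argmax ties are broken by
    population label order and flagged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    labels = result.populations
    order = sorted(range(len(labels)), key=lambda k: labels[k])
    outcomes = []
    for i, sid in enumerate(result.sample_ids):
        row = result.q[i]
        qmax = float(row.max())
        tied_ks = [k for k in order if row[k] == qmax]
        best = labels[tied_ks[0]]
        if qmax > threshold:
            outcomes.append(AssignmentOutcome(sid, best, qmax, threshold,
                                              tied=len(tied_ks) > 1))
        else:
            outcomes.append(AssignmentOutcome(sid, UNASSIGNED, qmax, threshold))
    return outcomes


def rates(
    outcomes: Sequence[AssignmentOutcome], truth: Mapping[str, str]
) -> tuple[float, float]:
    """(assignment rate, misassignment rate) for outcomes with known truth.

    The misassignment rate is taken over assigned queries only and is NaN
    when no query was assigned.
    """
    if not outcomes:
        raise ValueError("no outcomes")
    assigned = [o for o in outcomes if o.population is not None]
    assignment_rate = len(assigned) / len(outcomes)
    if not assigned:
        return assignment_rate, float("nan")
    wrong = sum(1 for o in assigned if o.population != truth[o.sample_id])
    return assignment_rate, wrong / len(assigned)


def rate_curve(
    result: AncestryProportions,
    truth: Mapping[str, str],
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assignment and misassignment rates across an ancestry-threshold grid.

    Returns a frame with columns threshold, assignment_rate,
    misassignment_rate and n_assigned, suitable for plotting rate-vs-
    threshold curves; the assignment rate is non-increasing in t.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    rows = []
    for t in np.asarray(thresholds, dtype=float):
        outcomes = assign(result, float(t))
        a, m = rates(outcomes, truth)
        n_assigned = sum(1 for o in outcomes if o.population is not None)
        rows.append((float(t), a, m, n_assigned))
    return pd.DataFrame(rows, columns=["threshold", "assignment_rate",
                                       "misassignment_rate", "n_assigned"])


def _loo_em(
    dataset: GenotypeDataset,
    panel,
    config: EmConfig,
) -> AncestryProportions:
    """Leave-one-out EM: each query's own calls are removed from its
    population's frequency estimate before its ancestry is estimated."""
    from .ancestry import ReferencePanel
    from .data import MISSING

    results = []
    pop_index = {p: k for k, p in enumerate(panel.populations)}
    for i, s in enumerate(dataset.samples):
        g = dataset.genotypes[i]
        k = pop_index.get(s.population)
        freqs = panel.freqs
        if k is not None:
            called = g != MISSING
            y = panel.allele_counts[k].astype(np.float64)
            n = panel.allele_totals[k].astype(np.float64)
            y_adj = y - np.where(called, g, 0)
            n_adj = n - 2.0 * called
            f_adj = (y_adj + 1.0) / (n_adj + 2.0)
            freqs = panel.freqs.copy()
            freqs[k] = f_adj
        sub = ReferencePanel(panel.populations, panel.marker_ids, freqs,
                             panel.allele_counts, panel.allele_totals)
        results.append(supervised_em(g[None, :], sub, config))
    q = np.vstack([r.q for r in results])
    return AncestryProportions(
        dataset.sample_ids,
        list(panel.populations),
        q,
        np.concatenate([r.loglikelihood for r in results]),
        np.concatenate([r.iterations for r in results]),
        np.concatenate([r.converged for r in results]),
    )


def self_assignment_experiment(
    dataset: GenotypeDataset,
    subset_sizes: Sequence[int],
    epsilons: Sequence[float] = (0.01, 0.1, 1.0),
    thresholds: np.ndarray | None = None,
    seed: int = 0,
    min_individuals: int = 15,
    leave_one_out: bool = False,
) -> dict[tuple[int, float], pd.DataFrame]:
    """Self-assignment evaluation over marker-subset sizes and epsilons.

    For each subset size, markers are sampled uniformly without
    replacement under the seed; the reference panel is built from all
    individuals of qualifying populations, and every individual of those
    populations is assigned back against it.  One rate curve is returned
    per (size, epsilon) pair.
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = default_thresholds()
    curves: dict[tuple[int, float], pd.DataFrame] = {}
    for size in subset_sizes:
        if size > dataset.n_markers:
            raise ValueError(
                f"subset size {size} exceeds marker count {dataset.n_markers}"
            )
        if size == dataset.n_markers:
            idx = np.arange(dataset.n_markers)
        else:
            idx = np.sort(rng.choice(dataset.n_markers, size, replace=False))
        sub = dataset.take(marker_indices=idx)
        panel = build_reference_panel(sub, min_individuals)
        eligible = set(panel.populations)
        queries = sub.select_populations(eligible)
        truth = {s.id: s.population for s in queries.samples}
        for eps in epsilons:
            config = EmConfig(epsilon=eps)
            if leave_one_out:
                result = _loo_em(queries, panel, config)
            else:
                result = supervised_em(queries, panel, config)
            curves[(int(size), float(eps))] = rate_curve(result, truth,
                                                         thresholds)
    return curves
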