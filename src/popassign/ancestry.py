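"""Supervised-clustering ancestry estimation.

Reference allele frequencies are estimated per population with Laplace
smoothing, f = (y + 1) / (n + 2), where y is the counted-allele copy count
and n the total allele count; smoothing keeps every frequency strictly
inside (0, 1) so log-likelihoods stay finite.  Ancestry proportions q of a
query individual are then estimated by an EM algorithm of the
FRAPPE/ADMIXTURE family with the frequencies held fixed (only q moves):
with dosage g_m at locus m and panel frequencies f_km,

    log L(q) = sum_m [ g_m * ln(sum_k q_k f_km)
                       + (2 - g_m) * ln(sum_k q_k (1 - f_km)) ]

    q'_k = (1 / 2M') * sum_m [ g_m * q_k f_km / sum_l q_l f_lm
                               + (2 - g_m) * q_k (1 - f_km) / sum_l q_l (1 - f_lm) ]

over the M' non-missing loci.  Iteration stops when the log-likelihood
improvement drops below the stopping tolerance epsilon; a loose epsilon
terminates quickly at some cost in accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset

__all__ = [
    "ReferencePanel",
    "EmConfig",
    "AncestryProportions",
    "build_reference_panel",
    "loglikelihood",
    "supervised_em",
    "ancestry_tables",
    "write_ancestry_outputs",
]

#: Default minimum population size for inclusion in a reference panel.
MIN_REFERENCE_INDIVIDUALS = 15


@dataclass
class ReferencePanel:
    """Per-population Laplace-smoothed allele frequencies on a marker set."""

    populations: list[str]
    marker_ids: list[str]
    freqs: np.ndarray          # (K, M), strictly inside (0, 1)
    allele_counts: np.ndarray  # (K, M) counted-allele copies y
    allele_totals: np.ndarray  # (K, M) total allele counts n
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def build_reference_panel(
    dataset: GenotypeDataset,
    min_individuals: int = MIN_REFERENCE_INDIVIDUALS,
) -> ReferencePanel:
    """Estimate smoothed allele frequencies for each qualifying population.

    Populations with fewer than ``min_individuals`` samples are excluded
    (and reported in ``excluded``); counts use only non-missing calls, so a
    population with no calls at a marker gets the symmetric prior f = 1/2.
    """
    by_pop: dict[str, list[int]] = {}
    for i, s in enumerate(dataset.samples):
        by_pop.setdefault(s.population, []).append(i)
    qualifying = sorted(p for p, idx in by_pop.items()
                        if len(idx) >= min_individuals)
    excluded = {p: len(idx) for p, idx in sorted(by_pop.items())
                if len(idx) < min_individuals}
    if not qualifying:
        raise ValueError(
            f"no population reaches the reference floor of {min_individuals} "
            "individuals"
        )
    K, M = len(qualifying), dataset.n_markers
    y = np.zeros((K, M), dtype=np.int64)
    n = np.zeros((K, M), dtype=np.int64)
    g = dataset.genotypes
    for k, pop in enumerate(qualifying):
        rows = np.asarray(by_pop[pop])
        sub = g[rows, :]
        called = sub != MISSING
        y[k] = np.where(called, sub, 0).sum(axis=0)
        n[k] = 2 * called.sum(axis=0)
    freqs = (y + 1.0) / (n + 2.0)
    return ReferencePanel(qualifying, list(dataset.marker_ids), freqs, y, n,
                          excluded)


@dataclass
class EmConfig:
    """EM settings: stopping tolerance epsilon on the log-likelihood
    improvement (presets 0.01, 0.1 and 1 are typical; any positive value is
    allowed), an iteration cap, and the initialisation rule."""

    epsilon: float = 0.1
    max_iterations: int = 10_000
    init: str = "uniform"  # "uniform" or "random" (seeded Dirichlet)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init not in ("uniform", "random"):
            raise ValueError("init must be 'uniform' or 'random'")


@dataclass
class AncestryProportions:
    """Per-query ancestry vectors on the K-simplex plus fit diagnostics."""

    sample_ids: list[str]
    populations: list[str]
    q: np.ndarray            # (n_query, K), rows sum to 1
    loglikelihood: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    trace: list[np.ndarray] | None = None  # per-query log-likelihood paths


def _query_matrix(
    queries: GenotypeDataset | np.ndarray, panel: ReferencePanel
) -> tuple[np.ndarray, list[str]]:
    if isinstance(queries, GenotypeDataset):
        if queries.marker_ids != panel.marker_ids:
            order = {m: j for j, m in enumerate(queries.marker_ids)}
            try:
                idx = [order[m] for m in panel.marker_ids]
            except KeyError as e:
                raise ValueError(
                    f"query dataset lacks panel marker {e.args[0]}"
                ) from None
            g = queries.genotypes[:, idx]
        else:
            g = queries.genotypes
        return np.asarray(g), queries.sample_ids
    g = np.atleast_2d(np.asarray(queries))
    if g.shape[1] != panel.n_markers:
        raise ValueError(
            f"query matrix has {g.shape[1]} loci, panel has {panel.n_markers}"
        )
    return g, [f"query{i}" for i in range(g.shape[0])]


def loglikelihood(
    g: np.ndarray, q: np.ndarray, panel: ReferencePanel | np.ndarray
) -> float:
    """Log-likelihood of one query's dosages under ancestry vector ``q``.

    Missing loci contribute nothing (an all-missing query scores 0).
    """
    f = panel.freqs if isinstance(panel, ReferencePanel) else np.asarray(panel)
    g = np.asarray(g, dtype=np.int64)
    q = np.asarray(q, dtype=np.float64)
    called = g != MISSING
    if not called.any():
        return 0.0
    a = q @ f[:, called]
    b = q @ (1.0 - f[:, called])
    gm = g[called]
    return float(np.sum(gm * np.log(a) + (2 - gm) * np.log(b)))


def supervised_em(
    queries: GenotypeDataset | np.ndarray,
    panel: ReferencePanel,
    config: EmConfig | None = None,
    return_trace: bool = False,
) -> AncestryProportions:
    """Estimate ancestry proportions for each query against a fixed panel.

    Queries are optimised independently (the likelihood factorises over
    individuals once frequencies are fixed) but the updates are batched.
    Each query iterates until its own log-likelihood improvement falls
    below epsilon or the iteration cap is hit; ``converged`` records which.
    """
    config = config or EmConfig()
    G, sample_ids = _query_matrix(queries, panel)
    n, M = G.shape
    K = panel.n_populations
    if K == 0:
        raise ValueError("panel has no populations")

    miss = G == MISSING
    m_prime = (~miss).sum(axis=1)
    if (m_prime == 0).any():
        bad = [sample_ids[i] for i in np.flatnonzero(m_prime == 0)]
        raise ValueError(
            f"queries with no genotyped loci shared with the panel: {bad}"
        )
    Gp = np.where(miss, 0, G).astype(np.float64)
    Gm = np.where(miss, 0, 2 - G).astype(np.float64)
    F = panel.freqs
    Fc = 1.0 - F

    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        Q = rng.dirichlet(np.ones(K), size=n)
    else:
        Q = np.full((n, K), 1.0 / K)

    def _ll(Qm: np.ndarray, rows: np.ndarray | slice = slice(None)) -> np.ndarray:
        A = Qm @ F
        B = Qm @ Fc
        return np.einsum("ij,ij->i", Gp[rows], np.log(A)) + \
            np.einsum("ij,ij->i", Gm[rows], np.log(B))

    ll = _ll(Q)
    traces = [[v] for v in ll] if return_trace else None
    iterations = np.zeros(n, dtype=np.int64)
    converged = np.zeros(n, dtype=bool)
    if K == 1:
        return AncestryProportions(sample_ids, list(panel.populations),
                                   np.ones((n, 1)), ll, iterations,
                                   np.ones(n, dtype=bool),
                                   [np.asarray(t) for t in traces] if traces else None)

    active = np.ones(n, dtype=bool)
    for _ in range(config.max_iterations):
        idx = np.flatnonzero(active)
        Qa = Q[idx]
        A = Qa @ F
        B = Qa @ Fc
        T = (Gp[idx] / A) @ F.T + (Gm[idx] / B) @ Fc.T
        Qn = Qa * T / (2.0 * m_prime[idx, None])
        Qn /= Qn.sum(axis=1, keepdims=True)
        ll_new = _ll(Qn, idx)
        Q[idx] = Qn
        iterations[idx] += 1
        if traces is not None:
            for pos, i in enumerate(idx):
                traces[i].append(ll_new[pos])
        delta = ll_new - ll[idx]
        done = delta < config.epsilon
        converged[idx[done]] = True
        ll[idx] = ll_new
        active[idx[done]] = False
        if not active.any():
            break

    return AncestryProportions(
        sample_ids, list(panel.populations), Q, ll, iterations, converged,
        [np.asarray(t) for t in traces] if traces else None,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def ancestry_tables(
    result: AncestryProportions, top_n: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-results and summary tables.

    The results table holds the complete q matrix (one population per
    column, stable order) with the final log-likelihood, iteration count
    and convergence flag; the summary lists each query's top populations
    by ancestry proportion.
    """
    results = pd.DataFrame(result.q, columns=result.populations)
    results.insert(0, "sample", result.sample_ids)
    results["loglikelihood"] = result.loglikelihood
    results["iterations"] = result.iterations
    results["converged"] = result.converged

    rows = []
    for i, sid in enumerate(result.sample_ids):
        order = sorted(range(len(result.populations)),
                       key=lambda k: (-result.q[i, k], result.populations[k]))
        for rank, k in enumerate(order[:top_n], 1):
            rows.append((sid, rank, result.populations[k],
                         float(result.q[i, k])))
    summary = pd.DataFrame(rows, columns=["sample", "rank", "population",
                                          "ancestry"])
    return results, summary


def write_ancestry_outputs(
    result: AncestryProportions,
    results_target: str | Path | IO[str],
    summary_target: str | Path | IO[str],
    top_n: int = 5,
) -> None:
    """Write ancestry_results.tsv and ancestry_summary.tsv."""
    results, summary = ancestry_tables(result, top_n)
    results.to_csv(results_target, sep="\t", index=False)
    summary.to_csv(summary_target, sep="\t", index=False)


def read_ancestry_results(source: str | Path | IO[str]) -> pd.DataFrame:
    """Parse an ancestry_results.tsv back into a DataFrame."""
    return pd.read_csv(source, sep="\t")
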