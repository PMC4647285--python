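"""Seeded synthetic genotype panels under the Balding-Nichols model.

The generator produces differentiated reference populations and admixed
query individuals with known ancestry.  Per marker, an ancestral allele
frequency p is drawn uniformly from a configurable range; each population's
frequency is then Beta-distributed around p with shape parameters
p(1-F)/F and (1-p)(1-F)/F, so F plays the role of FST: the expected
population frequency is p and its variance is F p (1-p).  Genotypes are two
independent allele draws per individual (unlinked loci, no LD).  Admixed
individuals draw, for every allele copy, first a source population from
their ancestry vector q* and then the allele from that population's
frequency.  All randomness flows through a single seeded NumPy generator,
so a seed pins the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import MISSING, GenotypeDataset, Marker, Sample

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_admixed",
    "inject_missingness",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic panel.

    Defaults describe a 10-population panel of 20 individuals each at
    10,000 unlinked SNPs with FST 0.1 and no missingness — a desk-scale
    analog of a diverged multi-breed reference panel.
    """

    n_populations: int = 10
    n_individuals: int = 20
    n_markers: int = 10_000
    fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    #: admixture design: list of (q* vector over the reference populations,
    #: number of admixed individuals to draw)
    admixed: list[tuple[Sequence[float], int]] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_individuals, self.n_markers) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("ancestral_freq_range must be an interval in [0, 1]")
        for q, count in self.admixed:
            q = np.asarray(q, dtype=float)
            if q.shape != (self.n_populations,) or q.min() < 0 or \
                    abs(q.sum() - 1.0) > 1e-9:
                raise ValueError("admixture vectors must lie on the simplex")
            if count < 1:
                raise ValueError("admixed counts must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


def _standard_markers(n_markers: int) -> list[Marker]:
    width = len(str(n_markers))
    return [Marker(f"M{j + 1:0{width}d}", "1", j + 1, ("A", "G"))
            for j in range(n_markers)]


def _pop_label(k: int) -> str:
    return f"POP{k + 1:02d}"


def simulate_reference(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Draw the reference populations; returns (dataset, true frequencies).

    The true frequency matrix has shape (n_populations, n_markers) and
    holds the Balding-Nichols draws the genotypes were sampled from.
    """
    rng = np.random.default_rng(config.seed)
    K, N, M = config.n_populations, config.n_individuals, config.n_markers
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=M)
    a = p * (1.0 - config.fst) / config.fst
    b = (1.0 - p) * (1.0 - config.fst) / config.fst
    freqs = rng.beta(a, b, size=(K, M))
    freqs = np.clip(freqs, 1e-12, 1.0 - 1e-12)

    genotypes = np.empty((K * N, M), dtype=np.int8)
    samples = []
    for k in range(K):
        genotypes[k * N:(k + 1) * N] = rng.binomial(
            2, freqs[k], size=(N, M)).astype(np.int8)
        pop = _pop_label(k)
        samples.extend(Sample(f"{pop}_I{i + 1:03d}", pop) for i in range(N))
    dataset = GenotypeDataset(samples, _standard_markers(M), genotypes)
    if config.missing_rate > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate,
            seed=int(rng.integers(2**31)),
        )
    return dataset, freqs


def simulate_admixed(
    freqs: np.ndarray,
    q_star: Sequence[float],
    n_individuals: int,
    seed: int,
    population: str = "ADMIX",
    id_prefix: str | None = None,
) -> GenotypeDataset:
    """Draw admixed individuals with known ancestry vector ``q_star``.

    Each allele copy at each locus picks a source population with
    probabilities q*, then samples the allele from that population's
    frequency; the expected dosage at locus m is thus 2 * sum_k q*_k f_km.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q_star, dtype=float)
    K, M = freqs.shape
    if q.shape != (K,) or q.min() < 0 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("q_star must be a simplex vector of length K")
    z = rng.choice(K, size=(n_individuals, M, 2), p=q)
    u = rng.random((n_individuals, M, 2))
    alleles = u < freqs[z, np.arange(M)[None, :, None]]
    genotypes = alleles.sum(axis=2).astype(np.int8)
    prefix = id_prefix or population
    samples = [Sample(f"{prefix}_I{i + 1:03d}", population)
               for i in range(n_individuals)]
    return GenotypeDataset(samples, _standard_markers(M), genotypes)


def inject_missingness(
    dataset: GenotypeDataset, rate: float, seed: int
) -> GenotypeDataset:
    """Set each call to missing independently with the given probability."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = dataset.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.genotypes.shape) < rate
    out.genotypes[mask] = MISSING
    return out


def simulate_study(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, np.ndarray, dict[str, np.ndarray]]:
    """Reference populations plus any configured admixed individuals.

    Returns (combined dataset, true frequency matrix, truth) where truth
    maps each sample id to its designed ancestry vector (a unit vector for
    reference individuals).
    """
    reference, freqs = simulate_reference(config)
    truth: dict[str, np.ndarray] = {}
    K = config.n_populations
    for i, s in enumerate(reference.samples):
        k = int(s.population[3:]) - 1
        truth[s.id] = np.eye(K)[k]
    if not config.admixed:
        return reference, freqs, truth

    rng = np.random.default_rng(config.seed + 1)
    parts = [reference]
    for group_idx, (q_star, count) in enumerate(config.admixed):
        pop = f"ADM{group_idx + 1:02d}"
        ds = simulate_admixed(freqs, q_star, count,
                              seed=int(rng.integers(2**31)), population=pop)
        if config.missing_rate > 0:
            ds = inject_missingness(ds, config.missing_rate,
                                    seed=int(rng.integers(2**31)))
        for s in ds.samples:
            truth[s.id] = np.asarray(q_star, dtype=float)
        parts.append(ds)

    samples = [s for part in parts for s in part.samples]
    genotypes = np.vstack([part.genotypes for part in parts])
    combined = GenotypeDataset(samples, _standard_markers(config.n_markers),
                               genotypes)
    return combined, freqs, truth
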