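"""Principal component analysis of genotype matrices.

Genotypes are coded as counted-allele dosages, missing calls are
mean-imputed per marker, each marker is mean-centred and (optionally)
divided by sqrt(p(1-p)) with p the counted-allele frequency — the usual
allele-frequency normalisation for SNP PCA, which equalises drift variance
across frequencies.  Monomorphic and all-missing markers carry no
information and are dropped before the decomposition.  Output files follow
the two-file text layout (``output.pca.evec`` with an eigenvalue header
line, ``output.eval`` with one eigenvalue per line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .data import MISSING, GenotypeDataset

__all__ = ["PcaResult", "run_pca", "write_pca_outputs", "read_evec"]


@dataclass
class PcaResult:
    sample_ids: list[str]
    populations: list[str]
    coordinates: np.ndarray        # (n_samples, k) principal component scores
    eigenvectors: np.ndarray       # (n_samples, k), orthonormal columns
    eigenvalues: np.ndarray        # (k,), non-increasing
    variance_fractions: np.ndarray # (k,)
    marker_ids: list[str]          # markers actually used

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def run_pca(
    dataset: GenotypeDataset,
    n_components: int = 10,
    normalize: bool = True,
) -> PcaResult:
    """PCA of the samples of a genotype dataset.

    Components are defined up to sign.  If fewer informative markers (or
    samples) than requested components are available, the result is
    truncated with a warning.
    """
    if dataset.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = dataset.genotypes.astype(np.float64)
    miss = dataset.genotypes == MISSING
    called = ~miss
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_called > 0,
                        np.where(called, g, 0.0).sum(axis=0) / np.maximum(n_called, 1),
                        np.nan)
    p_hat = mean / 2.0
    informative = (n_called > 0) & (p_hat > 0.0) & (p_hat < 1.0)
    if informative.sum() < 2:
        raise ValueError("PCA needs at least 2 polymorphic markers")
    idx = np.flatnonzero(informative)
    x = np.where(miss, mean[None, :], g)[:, idx]
    x -= mean[idx][None, :]
    if normalize:
        x /= np.sqrt(p_hat[idx] * (1.0 - p_hat[idx]))[None, :]

    max_k = min(dataset.n_samples, idx.size)
    k = min(n_components, max_k)
    if k < n_components:
        warnings.warn(
            f"only {k} components available "
            f"({dataset.n_samples} samples, {idx.size} informative markers); "
            f"requested {n_components}",
            stacklevel=2,
        )
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (dataset.n_samples - 1)
    total = eigenvalues.sum()
    coords = u[:, :k] * s[:k]
    return PcaResult(
        sample_ids=dataset.sample_ids,
        populations=dataset.populations,
        coordinates=coords,
        eigenvectors=u[:, :k],
        eigenvalues=eigenvalues[:k],
        variance_fractions=eigenvalues[:k] / total if total > 0 else
        np.zeros(k),
        marker_ids=[dataset.markers[j].id for j in idx],
    )


def _opened(target: str | Path | IO[str]):
    if isinstance(target, (str, Path)):
        return open(target, "w"), True
    return target, False


def write_pca_outputs(
    result: PcaResult,
    evec_target: str | Path | IO[str],
    eval_target: str | Path | IO[str],
) -> None:
    """Write evec/eval text files.

    The evec file starts with a ``#eigvals:`` header listing the computed
    eigenvalues, followed by one line per sample (id, coordinates,
    population label); the eval file lists one eigenvalue per line.
    """
    stream, close = _opened(evec_target)
    try:
        vals = " ".join(f"{v:.6f}" for v in result.eigenvalues)
        stream.write(f"  #eigvals: {vals}\n")
        for i, sid in enumerate(result.sample_ids):
            coords = " ".join(f"{c: .6f}" for c in result.coordinates[i])
            stream.write(f"  {sid} {coords} {result.populations[i]}\n")
    finally:
        if close:
            stream.close()
    stream, close = _opened(eval_target)
    try:
        for v in result.eigenvalues:
            stream.write(f"{v:.6f}\n")
    finally:
        if close:
            stream.close()


def read_evec(source: str | Path | IO[str]):
    """Parse an evec file back into (ids, coordinates, populations, eigenvalues)."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) \
        else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    assert header[0] == "#eigvals:"
    eigenvalues = np.array([float(v) for v in header[1:]])
    ids, rows, pops = [], [], []
    for ln in lines[1:]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:-1]])
        pops.append(parts[-1])
    return ids, np.array(rows), pops, eigenvalues
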