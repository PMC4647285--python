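"""Core data model for diploid biallelic SNP genotype panels.

A :class:`GenotypeDataset` holds an ordered list of samples, an ordered list
of markers and a samples x markers matrix of diploid calls.  Calls are stored
as the dosage of each marker's *counted* allele (0, 1 or 2 copies), with
``MISSING`` (-1) for no-calls; together with the per-marker allele letters
this is equivalent to storing unordered nucleotide pairs, and it is the
representation every downstream computation (distances, allele frequencies,
ancestry likelihoods, PCA coding) consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

#: Sentinel dosage for a missing diploid call.
MISSING = -1

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

#: Strand-ambiguous allele pairs: indistinguishable from their complement.
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class FormatError(ValueError):
    """Malformed input text (wrong column counts, bad tokens...)."""


class GenotypeDataError(ValueError):
    """Structurally valid input with inconsistent genotype content."""


@dataclass
class Marker:
    """A biallelic SNP.

    ``alleles`` is an ordered pair ``(counted, other)``; the counted allele
    is the one whose copy number the dosage matrix records.  ``"0"`` stands
    for an unobserved allele (monomorphic or fully missing markers).
    """

    id: str
    chromosome: str
    position: int
    alleles: tuple[str, str] = ("0", "0")
    synonyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GenotypeDataError(
                f"marker {self.id}: position must be >= 1, got {self.position}"
            )

    @property
    def counted_allele(self) -> str:
        return self.alleles[0]

    @property
    def other_allele(self) -> str:
        return self.alleles[1]

    def location_class(self) -> str:
        """Classify the chromosome label: autosomal / sex / mitochondrial / other."""
        c = str(self.chromosome).upper()
        if c in {"MT", "M"}:
            return "mitochondrial"
        if c in {"X", "Y", "XY"}:
            return "sex"
        if c.isdigit():
            return "autosomal"
        return "other"


@dataclass
class Sample:
    id: str
    population: str
    project: str = ""
    flagged_misidentified: bool = False

    def __post_init__(self) -> None:
        if not self.population:
            raise GenotypeDataError(f"sample {self.id}: population label is empty")


class GenotypeDataset:
    """Samples x markers diploid genotype matrix plus metadata.

    Parameters
    ----------
    samples : sequence of :class:`Sample`
    markers : sequence of :class:`Marker`
    genotypes : array-like of shape (n_samples, n_markers)
        Counted-allele dosages in {0, 1, 2} or ``MISSING``.
    """

    def __init__(
        self,
        samples: Sequence[Sample],
        markers: Sequence[Marker],
        genotypes: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.markers = list(markers)
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape != (len(self.samples), len(self.markers)):
            raise GenotypeDataError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(g, (MISSING, 0, 1, 2))
        if bad.any():
            raise GenotypeDataError("genotype dosages must be in {-1, 0, 1, 2}")
        self.genotypes = g
        self._validate()

    def _validate(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeDataError("duplicate sample ids")
        mids = [m.id for m in self.markers]
        if len(set(mids)) != len(mids):
            raise GenotypeDataError("duplicate marker ids")
        primary = set(mids)
        for m in self.markers:
            if m.synonyms & primary:
                raise GenotypeDataError(
                    f"marker {m.id}: synonyms overlap primary marker ids"
                )
        # Non-missing calls must be expressible with the marker's two alleles.
        for j, m in enumerate(self.markers):
            col = self.genotypes[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            if m.counted_allele == "0":
                raise GenotypeDataError(
                    f"marker {m.id}: non-missing calls but no counted allele defined"
                )
            if m.other_allele == "0" and (obs < 2).any():
                raise GenotypeDataError(
                    f"marker {m.id}: calls carry an undefined second allele"
                )

    # ------------------------------------------------------------------ basics
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def populations(self) -> list[str]:
        """Per-sample population labels (parallel to ``samples``)."""
        return [s.population for s in self.samples]

    def population_labels(self) -> list[str]:
        """Distinct population labels in sorted order."""
        return sorted(set(self.populations))

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            [Sample(s.id, s.population, s.project, s.flagged_misidentified)
             for s in self.samples],
            [Marker(m.id, m.chromosome, m.position, m.alleles, set(m.synonyms))
             for m in self.markers],
            self.genotypes.copy(),
        )

    # --------------------------------------------------------------- selection
    def take(
        self,
        sample_indices: Sequence[int] | np.ndarray | None = None,
        marker_indices: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Order-preserving positional subset (copies metadata)."""
        si = np.arange(self.n_samples) if sample_indices is None else np.asarray(sample_indices)
        mi = np.arange(self.n_markers) if marker_indices is None else np.asarray(marker_indices)
        samples = [self.samples[i] for i in si]
        markers = [self.markers[j] for j in mi]
        g = self.genotypes[np.ix_(si, mi)] if len(si) and len(mi) else \
            np.zeros((len(si), len(mi)), dtype=np.int8)
        out = GenotypeDataset.__new__(GenotypeDataset)
        out.samples = [Sample(s.id, s.population, s.project, s.flagged_misidentified)
                       for s in samples]
        out.markers = [Marker(m.id, m.chromosome, m.position, m.alleles, set(m.synonyms))
                       for m in markers]
        out.genotypes = np.asarray(g, dtype=np.int8)
        return out

    def subset(
        self,
        sample_pred: Callable[[Sample], bool] | None = None,
        marker_pred: Callable[[Marker], bool] | None = None,
    ) -> "GenotypeDataset":
        """Subset by predicates over sample / marker metadata (order preserved).

        An empty selection yields an empty dataset, not an error.
        """
        si = [i for i, s in enumerate(self.samples)
              if sample_pred is None or sample_pred(s)]
        mi = [j for j, m in enumerate(self.markers)
              if marker_pred is None or marker_pred(m)]
        return self.take(si, mi)

    def select_populations(self, populations: Iterable[str]) -> "GenotypeDataset":
        keep = set(populations)
        return self.subset(sample_pred=lambda s: s.population in keep)

    def select_locations(self, classes: Iterable[str]) -> "GenotypeDataset":
        """Keep markers whose chromosome falls in the given location classes
        (subset of {"autosomal", "sex", "mitochondrial", "other"})."""
        keep = set(classes)
        return self.subset(marker_pred=lambda m: m.location_class() in keep)

    # ------------------------------------------------------------------ counts
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def sample_call_rates(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def marker_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - self.missing_mask().mean(axis=0)

    def counted_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled per-marker counted-allele copies ``y`` and total allele
        counts ``n`` (= 2 x genotyped diploids), over all samples."""
        g = self.genotypes
        called = g != MISSING
        y = np.where(called, g, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        return y.astype(np.int64), n.astype(np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Pooled counted-allele frequency per marker (NaN where no calls)."""
        y, n = self.counted_allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, y / np.maximum(n, 1), np.nan)

    def genotype_letters(self, i: int, j: int) -> tuple[str, str] | None:
        """Allele-letter pair for call (sample i, marker j); None if missing."""
        d = int(self.genotypes[i, j])
        if d == MISSING:
            return None
        a, b = self.markers[j].alleles
        return {2: (a, a), 1: (a, b), 0: (b, b)}[d]

    def genotypes_equal(self, other: "GenotypeDataset") -> bool:
        """Content equality of calls compared as unordered letter pairs,
        so it is immune to which allele each dataset counts."""
        if self.shape != other.shape:
            return False

        def letter_col(ds: "GenotypeDataset", j: int) -> list:
            a, b = ds.markers[j].alleles
            table = {MISSING: None, 2: (a, a), 1: tuple(sorted((a, b))),
                     0: (b, b)}
            return [table[int(d)] for d in ds.genotypes[:, j]]

        for j in range(self.n_markers):
            if letter_col(self, j) != letter_col(other, j):
                return False
        return True


# ---------------------------------------------------------------------------
# Allele reconciliation
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str:
    return _COMPLEMENT.get(allele, allele)


def _orientation(
    user_alleles: tuple[str, str], ref_alleles: tuple[str, str]
) -> int | None:
    """How user dosages map onto the reference orientation.

    Returns +1 (counted alleles agree), -1 (dosages must be flipped, d -> 2-d)
    or None when the pairs cannot be reconciled.  Strand flips are accepted
    only when the pair is not strand-ambiguous (A/T, C/G): for those,
    mismatched labels cannot be resolved and the marker is dropped.
    """
    ua = {a for a in user_alleles if a != "0"}
    ra = {a for a in ref_alleles if a != "0"}
    if not ua:
        return 1  # no observed user alleles; any orientation works
    r1, r2 = ref_alleles
    if ua <= ra or not ra:
        counted = user_alleles[0]
        if counted == r2:
            return -1
        return 1
    comp = {_complement(a) for a in ua}
    ambiguous = ua in _AMBIGUOUS_PAIRS or ra in _AMBIGUOUS_PAIRS
    if comp <= ra and not ambiguous:
        counted = _complement(user_alleles[0])
        if counted == r2:
            return -1
        return 1
    return None


# ---------------------------------------------------------------------------
# Marker curation: positional duplicates
# ---------------------------------------------------------------------------

@dataclass
class DuplicateGroup:
    """A set of markers sharing a (chromosome, position) pair."""

    chromosome: str
    position: int
    member_ids: list[str]
    kept_id: str | None
    concordant: bool


def deduplicate_by_position(
    dataset: GenotypeDataset,
) -> tuple[GenotypeDataset, list[DuplicateGroup]]:
    """Collapse markers that share a chromosome position.

    For each duplicated position the genotypes of all members are compared
    (in a common allele orientation, over calls non-missing in both).  If all
    members agree, one marker is kept and the dropped ids become its
    synonyms; if any pair disagrees — or alleles cannot be reconciled — the
    whole group is excluded from the curated dataset and reported as
    discordant, never silently merged.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for j, m in enumerate(dataset.markers):
        groups.setdefault((m.chromosome, m.position), []).append(j)

    keep: list[int] = []
    report: list[DuplicateGroup] = []
    extra_synonyms: dict[int, set[str]] = {}
    for (chrom, pos), idxs in groups.items():
        if len(idxs) == 1:
            keep.append(idxs[0])
            continue
        first = idxs[0]
        m0 = dataset.markers[first]
        concordant = True
        for j in idxs[1:]:
            mj = dataset.markers[j]
            orient = _orientation(mj.alleles, m0.alleles)
            if orient is None:
                concordant = False
                break
            a = dataset.genotypes[:, first]
            b = dataset.genotypes[:, j]
            if orient < 0:
                b = np.where(b == MISSING, MISSING, 2 - b)
            both = (a != MISSING) & (b != MISSING)
            if not np.array_equal(a[both], b[both]):
                concordant = False
                break
        member_ids = [dataset.markers[j].id for j in idxs]
        if concordant:
            keep.append(first)
            syn = set(member_ids[1:])
            for j in idxs[1:]:
                syn |= dataset.markers[j].synonyms
            extra_synonyms[first] = syn
            report.append(DuplicateGroup(chrom, pos, member_ids, m0.id, True))
        else:
            report.append(DuplicateGroup(chrom, pos, member_ids, None, False))

    keep.sort()
    curated = dataset.take(marker_indices=keep)
    pos_of = {j: i for i, j in enumerate(keep)}
    for j, syn in extra_synonyms.items():
        curated.markers[pos_of[j]].synonyms |= syn
    return curated, report


# ---------------------------------------------------------------------------
# Merging on shared markers
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    n_shared: int
    dropped_unreconcilable: list[str]
    matched_via_synonym: list[str]


def merge_on_shared_markers(
    user: GenotypeDataset, reference: GenotypeDataset
) -> tuple[GenotypeDataset, MergeReport]:
    """Combine user and reference samples over their shared markers.

    Markers are matched by reference id or synonym; allele labels are
    reconciled to the reference's counted allele (dosages flipped or
    strand-complemented as needed).  Markers whose allele pairs cannot be
    reconciled — including strand-ambiguous A/T and C/G pairs with
    mismatched labels — are dropped and reported.
    """
    lookup: dict[str, int] = {}
    for j, m in enumerate(reference.markers):
        lookup[m.id] = j
        for s in m.synonyms:
            lookup.setdefault(s, j)

    pairs: list[tuple[int, int]] = []  # (user index, reference index)
    via_synonym: list[str] = []
    for ju, mu in enumerate(user.markers):
        jr = lookup.get(mu.id)
        if jr is None:
            for s in mu.synonyms:
                jr = lookup.get(s)
                if jr is not None:
                    break
        if jr is not None:
            pairs.append((ju, jr))
            if mu.id != reference.markers[jr].id:
                via_synonym.append(mu.id)
    if not pairs:
        raise GenotypeDataError("no shared markers between the two datasets")

    # Reference marker order is canonical for the merged dataset.
    pairs.sort(key=lambda p: p[1])
    dropped: list[str] = []
    kept_pairs: list[tuple[int, int, int]] = []
    for ju, jr in pairs:
        orient = _orientation(user.markers[ju].alleles,
                              reference.markers[jr].alleles)
        if orient is None:
            dropped.append(reference.markers[jr].id)
        else:
            kept_pairs.append((ju, jr, orient))
    if not kept_pairs:
        raise GenotypeDataError("no reconcilable shared markers")

    markers = []
    gu = np.empty((user.n_samples, len(kept_pairs)), dtype=np.int8)
    gr = np.empty((reference.n_samples, len(kept_pairs)), dtype=np.int8)
    for k, (ju, jr, orient) in enumerate(kept_pairs):
        mr = reference.markers[jr]
        syn = set(mr.synonyms)
        if user.markers[ju].id != mr.id:
            syn.add(user.markers[ju].id)
        markers.append(Marker(mr.id, mr.chromosome, mr.position, mr.alleles, syn))
        col = user.genotypes[:, ju]
        if orient < 0:
            col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
        gu[:, k] = col
        gr[:, k] = reference.genotypes[:, jr]

    taken = {s.id for s in reference.samples}
    samples = []
    for s in user.samples:  # colliding user ids get a _Q suffix
        sid = s.id
        while sid in taken:
            sid += "_Q"
        taken.add(sid)
        samples.append(Sample(sid, s.population, s.project,
                              s.flagged_misidentified))
    samples += [Sample(s.id, s.population, s.project, s.flagged_misidentified)
                for s in reference.samples]
    merged = GenotypeDataset(samples, markers, np.vstack([gu, gr]))
    return merged, MergeReport(len(kept_pairs), dropped, via_synonym)
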