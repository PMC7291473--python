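"""Whittaker beta diversity, Shannon index, and barcoding-gap analysis.

The dissimilarity between two binary marker profiles is Whittaker's pairwise
beta-diversity index,

    bW = S / a_bar - 1,

where S is the number of markers present in the union of the pair and a_bar
the mean per-sample marker count.  Writing a for shared markers and b, c for
the private markers of each sample, this is (b + c) / (2a + b + c): 0 for
identical profiles, 1 for disjoint ones (on binary data it coincides with
the Sorensen dissimilarity).

The barcoding-gap analysis partitions all pairwise values into intra-specific
and inter-specific sets and measures how much the two distributions overlap:
a small overlap means profiles identify species reliably.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from skbio import DistanceMatrix

from .binning import MarkerMatrix
from .errors import DegenerateProfileError, TBPKitError
from .fragment_io import SampleMetadata

__all__ = [
    "whittaker_pairwise",
    "dissimilarity_matrix",
    "shannon_index",
    "GapAnalysisResult",
    "partition_intra_inter",
]


def whittaker_pairwise(x: Sequence[int], y: Sequence[int]) -> float:
    """Whittaker dissimilarity between two binary presence/absence rows."""
    xa = np.asarray(x)
    ya = np.asarray(y)
    if xa.shape != ya.shape:
        raise TBPKitError(f"rows differ in length: {xa.shape} vs {ya.shape}")
    xb = xa.astype(bool)
    yb = ya.astype(bool)
    if not xb.any() or not yb.any():
        raise DegenerateProfileError(
            "Whittaker dissimilarity is undefined for an all-zero profile "
            "(mean marker count degenerates)"
        )
    a = int((xb & yb).sum())
    b = int((xb & ~yb).sum())
    c = int((~xb & yb).sum())
    return (b + c) / (2 * a + b + c)


def dissimilarity_matrix(matrix: MarkerMatrix) -> DistanceMatrix:
    """All pairwise Whittaker dissimilarities of a marker matrix.

    Returns a symmetric, zero-diagonal :class:`skbio.DistanceMatrix` whose
    ids are the sample codes.  Missing cells and all-zero rows are rejected
    with the offending sample named.
    """
    if len(matrix.samples) < 2:
        raise TBPKitError("need at least 2 samples for a dissimilarity matrix")
    v = matrix.values
    nan_rows = [s for s, row in zip(matrix.samples, v) if np.isnan(row).any()]
    if nan_rows:
        raise TBPKitError(
            f"samples with missing region data: {nan_rows}; "
            "combine regions with how='inner' or drop them first"
        )
    row_sums = v.sum(axis=1)
    zero = [s for s, r in zip(matrix.samples, row_sums) if r == 0]
    if zero:
        raise DegenerateProfileError(f"all-zero marker profile for sample(s): {zero}")
    # 2a + b + c equals the sum of the two row totals; b + c is that sum
    # minus twice the shared count
    shared = v @ v.T
    totals = row_sums[:, None] + row_sums[None, :]
    with np.errstate(invalid="ignore"):
        d = (totals - 2 * shared) / totals
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=matrix.samples)


def shannon_index(
    matrix: MarkerMatrix,
    samples: Sequence[str] | None = None,
    *,
    convention: str,
) -> float:
    """Shannon diversity H of a group of samples' marker incidences.

    The only implemented convention, ``"presence-frequency"``, takes
    p_i = (presences of marker i within the group) / (total presences in the
    group) and returns H = -sum p_i ln p_i (natural log).  The convention is
    a required keyword so results are never silently conventional: the
    literature rarely states which frequencies its Shannon values are based
    on, and values are not comparable across conventions.
    """
    if convention != "presence-frequency":
        raise TBPKitError(
            f"unknown Shannon convention {convention!r}; "
            "implemented: 'presence-frequency'"
        )
    sub = matrix if samples is None else matrix.restrict(samples)
    counts = np.nansum(sub.values, axis=0)
    total = counts.sum()
    if total <= 0:
        raise TBPKitError("group has no marker presences; Shannon index undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class GapAnalysisResult:
    """Intra- vs inter-specific dissimilarity partition and their overlap."""

    intra: np.ndarray
    inter: np.ndarray
    intra_pairs: list[tuple[str, str]]
    inter_pairs: list[tuple[str, str]]

    @property
    def intra_range(self) -> tuple[float, float]:
        return float(self.intra.min()), float(self.intra.max())

    @property
    def inter_range(self) -> tuple[float, float]:
        return float(self.inter.min()), float(self.inter.max())

    @property
    def overlap_interval(self) -> tuple[float, float] | None:
        """Closed interval [min(inter), max(intra)], or None when empty."""
        lo, hi = float(self.inter.min()), float(self.intra.max())
        return (lo, hi) if lo <= hi else None

    @property
    def overlap_fraction(self) -> float:
        """Fraction of all observations falling inside the overlap interval."""
        iv = self.overlap_interval
        if iv is None:
            return 0.0
        lo, hi = iv
        pooled = np.concatenate([self.intra, self.inter])
        return float(((pooled >= lo) & (pooled <= hi)).mean())

    def summary(self) -> dict:
        return {
            "n_intra": int(self.intra.size),
            "n_inter": int(self.inter.size),
            "intra_range": list(self.intra_range),
            "inter_range": list(self.inter_range),
            "overlap_interval": (
                None if self.overlap_interval is None else list(self.overlap_interval)
            ),
            "overlap_fraction": self.overlap_fraction,
        }


def partition_intra_inter(
    d: DistanceMatrix,
    metadata: Iterable[SampleMetadata] | Mapping[str, str],
) -> GapAnalysisResult:
    """Split pairwise dissimilarities into intra- and inter-specific sets.

    ``metadata`` maps each sample to a species label (either a mapping or a
    list of :class:`SampleMetadata`).  Requires at least two species and at
    least one species with two samples, otherwise one of the partitions is
    empty and the gap is undefined.
    """
    if isinstance(metadata, Mapping):
        species = dict(metadata)
    else:
        species = {m.sample_code: m.species for m in metadata}
    missing = [s for s in d.ids if s not in species or not species[s]]
    if missing:
        raise TBPKitError(f"samples without a species label: {missing}")
    labels = [species[s] for s in d.ids]
    if len(set(labels)) < 2:
        raise TBPKitError("need >= 2 species for an intra/inter partition")

    intra_v: list[float] = []
    inter_v: list[float] = []
    intra_p: list[tuple[str, str]] = []
    inter_p: list[tuple[str, str]] = []
    ids = list(d.ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            val = float(d[ids[i], ids[j]])
            if labels[i] == labels[j]:
                intra_v.append(val)
                intra_p.append((ids[i], ids[j]))
            else:
                inter_v.append(val)
                inter_p.append((ids[i], ids[j]))
    if not intra_v:
        raise TBPKitError(
            "no intra-specific pairs (every species has a single sample); "
            "intra range undefined"
        )
    return GapAnalysisResult(
        intra=np.asarray(intra_v),
        inter=np.asarray(inter_v),
        intra_pairs=intra_p,
        inter_pairs=inter_p,
    )
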