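"""Ascending-size marker binning and the binary presence/absence matrix.

Consensus peak sizes from many samples are pooled, sorted ascending, and cut
into bins wherever the gap between consecutive sizes exceeds a tolerance
(single-linkage clustering with a gap cut).  Each bin is one dominant marker;
a sample scores 1 for a bin if it contributed a peak to it, else 0.  The
resulting samples x markers 0/1 matrix is the input of every downstream
diversity and clustering step.

Single-linkage chaining means a dense run of sizes can produce one wide bin;
bins wider than twice the gap tolerance are flagged with a warning so the
user can inspect them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TBPKitError
from .qc import ConsensusProfile

__all__ = [
    "MarkerBin",
    "MarkerMatrix",
    "bin_markers",
    "combine_regions",
    "peak_count_summary",
    "polymorphic_count",
]


@dataclass
class MarkerBin:
    """One binned marker: a cluster of near-identical amplicon sizes."""

    region: str
    center_bp: float
    min_bp: float
    max_bp: float
    members: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        # repr() round-trips floats exactly, keeping matrix CSV I/O lossless
        return f"{self.region}|{self.center_bp!r}"

    @classmethod
    def from_label(cls, label: str) -> "MarkerBin":
        region, _, center = label.rpartition("|")
        c = float(center)
        return cls(region=region, center_bp=c, min_bp=c, max_bp=c)


class MarkerMatrix:
    """Samples x binned markers presence/absence matrix.

    Cells are 1.0/0.0, or NaN where a sample was not assayed for a marker's
    region (possible only after an outer-join :func:`combine_regions`).
    """

    def __init__(self, samples: Sequence[str], bins: Sequence[MarkerBin], values):
        self.samples = list(samples)
        self.bins = list(bins)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.bins)):
            raise TBPKitError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.bins)} bins"
            )
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            raise TBPKitError("marker matrix cells must be 0, 1 or missing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for b in self.bins:
            if b.region not in seen:
                seen.append(b.region)
        return seen

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.samples, columns=[b.label for b in self.bins]
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        bins = [MarkerBin.from_label(c) for c in df.columns]
        return cls(list(df.index), bins, df.to_numpy(dtype=float))

    def restrict(self, samples: Sequence[str]) -> "MarkerMatrix":
        idx = [self.samples.index(s) for s in samples]
        return MarkerMatrix(list(samples), self.bins, self.values[idx])

    def region_submatrix(self, region: str) -> "MarkerMatrix":
        cols = [j for j, b in enumerate(self.bins) if b.region == region]
        if not cols:
            raise TBPKitError(f"no markers for region {region!r}")
        return MarkerMatrix(
            self.samples, [self.bins[j] for j in cols], self.values[:, cols]
        )

    def row_counts(self) -> pd.Series:
        return pd.Series(
            np.nansum(self.values, axis=1).astype(int), index=self.samples
        )


def bin_markers(
    profiles: Sequence[ConsensusProfile], gap_tol_bp: float = 1.0
) -> tuple[list[MarkerBin], MarkerMatrix]:
    """Bin one region's consensus profiles into markers and score the matrix.

    All (sample, size) pairs are pooled and sorted ascending; a new bin
    starts whenever the gap to the previous size exceeds ``gap_tol_bp``.
    If one sample lands twice in a bin it still scores a single presence
    (the matrix is binary by definition) and a collision warning is issued.
    """
    if gap_tol_bp <= 0:
        raise TBPKitError(f"gap_tol_bp must be positive, got {gap_tol_bp}")
    regions = {p.intron_region for p in profiles}
    if len(regions) > 1:
        raise TBPKitError(f"profiles mix regions {sorted(regions)}; bin one region at a time")
    samples = [p.sample_code for p in profiles]
    if len(set(samples)) != len(samples):
        raise TBPKitError("duplicate sample codes among profiles")
    if not profiles:
        return [], MarkerMatrix([], [], np.empty((0, 0)))
    region = next(iter(regions))

    pooled = sorted(
        ((peak.size_bp, p.sample_code) for p in profiles for peak in p.peaks),
        key=lambda t: (t[0], t[1]),
    )
    clusters: list[list[tuple[float, str]]] = []
    for entry in pooled:
        if clusters and entry[0] - clusters[-1][-1][0] <= gap_tol_bp:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])

    bins: list[MarkerBin] = []
    for cluster in clusters:
        members: dict[str, float] = {}
        for size, code in cluster:
            if code in members:
                warnings.warn(
                    f"sample {code} contributed two peaks ({members[code]}, {size}) "
                    f"to one bin near {size:.1f} bp; scored as a single presence",
                    stacklevel=2,
                )
                continue
            members[code] = size
        sizes = [s for s, _ in cluster]
        b = MarkerBin(
            region=region,
            center_bp=float(np.mean(sizes)),
            min_bp=min(sizes),
            max_bp=max(sizes),
            members=members,
        )
        if b.max_bp - b.min_bp > 2 * gap_tol_bp:
            warnings.warn(
                f"bin at {b.center_bp:.1f} bp spans {b.max_bp - b.min_bp:.2f} bp "
                f"(> 2x gap tolerance); single-linkage chaining suspected",
                stacklevel=2,
            )
        bins.append(b)

    values = np.zeros((len(samples), len(bins)))
    index = {code: i for i, code in enumerate(samples)}
    for j, b in enumerate(bins):
        for code in b.members:
            values[index[code], j] = 1.0
    return bins, MarkerMatrix(samples, bins, values)


def combine_regions(
    m1: MarkerMatrix, m2: MarkerMatrix, how: str = "inner"
) -> MarkerMatrix:
    """Concatenate the marker matrices of the two intron regions column-wise.

    With ``how='inner'`` (default) the sample sets must be identical and the
    row order of ``m1`` is kept.  With ``how='outer'`` the union of samples
    is used and cells of a missing region are set to NaN, with a warning
    naming the affected samples.  Disjoint sample sets are always an error.
    """
    s1, s2 = set(m1.samples), set(m2.samples)
    if not (s1 & s2):
        raise TBPKitError("sample sets of the two regions are disjoint; refusing to combine")
    if how == "inner":
        if s1 != s2:
            raise TBPKitError(
                "sample sets differ between regions: only in first="
                f"{sorted(s1 - s2)}, only in second={sorted(s2 - s1)}; "
                "use how='outer' to keep them with missing cells"
            )
        samples = list(m1.samples)
    elif how == "outer":
        samples = list(m1.samples) + [s for s in m2.samples if s not in s1]
        partial = sorted((s1 | s2) - (s1 & s2))
        if partial:
            warnings.warn(
                f"samples missing one region, cells set to missing: {partial}",
                stacklevel=2,
            )
    else:
        raise TBPKitError(f"how must be 'inner' or 'outer', got {how!r}")

    n = len(samples)
    out = np.full((n, len(m1.bins) + len(m2.bins)), np.nan)
    for src, offset in ((m1, 0), (m2, len(m1.bins))):
        pos = {s: i for i, s in enumerate(src.samples)}
        for i, s in enumerate(samples):
            if s in pos:
                out[i, offset : offset + len(src.bins)] = src.values[pos[s]]
    return MarkerMatrix(samples, list(m1.bins) + list(m2.bins), out)


def peak_count_summary(profiles: Iterable[ConsensusProfile]) -> pd.DataFrame:
    """Per-sample consensus peak counts per region, plus their total.

    Mirrors the per-accession peak-number tables used to relate TBP peak
    number to ploidy: one row per sample, one column per region, and a
    ``total`` column summing them.
    """
    counts: dict[str, dict[str, int]] = {}
    for p in profiles:
        counts.setdefault(p.sample_code, {})[p.intron_region] = len(p)
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df[sorted(df.columns, key=lambda r: (r != "first", r))]
    df["total"] = df.sum(axis=1)
    df.index.name = "Sample"
    return df


def polymorphic_count(matrix: MarkerMatrix) -> tuple[int, float]:
    """Number and percentage of polymorphic markers.

    A marker is polymorphic when it is present in at least one sample and
    absent in at least one (missing cells are ignored).  Requires >= 2
    samples; polymorphism is undefined for a single profile.
    """
    if len(matrix.samples) < 2:
        raise TBPKitError("polymorphism is undefined for fewer than 2 samples")
    v = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        has_presence = np.nansum(v, axis=0) >= 1
        has_absence = np.nansum(1 - v, axis=0) >= 1
    n_poly = int((has_presence & has_absence).sum())
    return n_poly, 100.0 * n_poly / len(matrix.bins)
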