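"""Peak-height quality control and replicate consolidation.

CE-TBP scoring applies two height thresholds: peaks must exceed 50 RFU to be
recorded at all, and a run containing any peak above 32,000 RFU is saturated
("out of scale") and discarded wholesale.  Each sample is measured by four
runs (two independent amplifications x two dilutions); :func:`consolidate`
merges the surviving runs of one sample/region into a single consensus
profile, keeping only peaks that are reproducible across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Sequence

from .errors import NoDataError, TBPKitError
from .fragment_io import CERun

__all__ = [
    "FilterVerdict",
    "ConsensusPeak",
    "ConsensusProfile",
    "filter_run",
    "consolidate",
    "write_profiles",
    "read_profiles",
]

#: Peak heights must strictly exceed this to be recorded (RFU).
MIN_RFU_DEFAULT = 50.0
#: Any peak above this saturates the detector; the whole run is excluded (RFU).
MAX_RFU_DEFAULT = 32000.0


@dataclass
class FilterVerdict:
    """Result of height-filtering one run: the filtered run, or an exclusion."""

    run: CERun | None
    excluded: bool = False
    reason: str | None = None


def filter_run(
    run: CERun,
    min_rfu: float = MIN_RFU_DEFAULT,
    max_rfu: float = MAX_RFU_DEFAULT,
) -> FilterVerdict:
    """Apply the recording and out-of-scale height thresholds to one run.

    Peaks are kept only if their height *strictly exceeds* ``min_rfu``.
    If any peak exceeds ``max_rfu`` the entire run is excluded and the
    saturating peak is named in the exclusion reason.  Filtering is
    idempotent: a filtered run passes through unchanged.
    """
    if not (0 < min_rfu < max_rfu):
        raise TBPKitError(
            f"thresholds must satisfy 0 < min_rfu < max_rfu, got {min_rfu}, {max_rfu}"
        )
    for p in run.peaks:
        if p.height_rfu > max_rfu:
            return FilterVerdict(
                run=None,
                excluded=True,
                reason=(
                    f"out of scale: peak at {p.size_bp} bp reached "
                    f"{p.height_rfu} RFU (> {max_rfu})"
                ),
            )
    kept = [p for p in run.peaks if p.height_rfu > min_rfu]
    return FilterVerdict(
        run=CERun(
            run.sample_code,
            run.intron_region,
            run.amplification_id,
            run.dilution_id,
            peaks=kept,
            standard_ok=run.standard_ok,
        )
    )


@dataclass(frozen=True)
class ConsensusPeak:
    size_bp: float
    support: int
    mean_height_rfu: float | None = None


@dataclass
class ConsensusProfile:
    """The reproducible peak list of one sample/region after consolidation."""

    sample_code: str
    intron_region: str
    peaks: list[ConsensusPeak] = field(default_factory=list)

    @property
    def peak_sizes_bp(self) -> list[float]:
        return [p.size_bp for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def consolidate(
    runs: Sequence[CERun],
    size_tol_bp: float = 1.0,
    min_support: int = 2,
    require_both_amplifications: bool = True,
) -> ConsensusProfile:
    """Merge the (<=4) surviving runs of one sample/region into a consensus.

    Peaks pooled across runs are clustered by single linkage on size: a gap
    greater than ``size_tol_bp`` between consecutive sorted sizes starts a
    new cluster.  A cluster becomes a consensus peak only if it draws peaks
    from at least ``min_support`` distinct runs and — when both
    amplifications contributed surviving runs — from both amplifications;
    reproducibility across independent amplifications is the point of the
    replicate design.  The consensus size is the mean of the member sizes.

    The result is independent of the order in which runs are supplied, and
    raising ``min_support`` can only remove consensus peaks.
    """
    if not runs:
        raise NoDataError("no surviving runs to consolidate")
    if size_tol_bp <= 0:
        raise TBPKitError(f"size_tol_bp must be positive, got {size_tol_bp}")
    if min_support < 1:
        raise TBPKitError(f"min_support must be >= 1, got {min_support}")
    keys = {(r.sample_code, r.intron_region) for r in runs}
    if len(keys) != 1:
        raise TBPKitError(f"runs span multiple sample/region combinations: {keys}")
    sample_code, region = next(iter(keys))

    amps_present = {r.amplification_id for r in runs}
    # (size, height, run identity, amplification), pooled and sorted by size;
    # run identity included in the sort key for order-independence on ties
    pooled = sorted(
        (
            (p.size_bp, p.height_rfu, r.key, r.amplification_id)
            for r in runs
            for p in r.peaks
        ),
        key=lambda t: (t[0], t[2]),
    )

    clusters: list[list[tuple[float, float, tuple, str]]] = []
    for entry in pooled:
        if clusters and entry[0] - clusters[-1][-1][0] <= size_tol_bp:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])

    peaks: list[ConsensusPeak] = []
    for cluster in clusters:
        run_ids = {e[2] for e in cluster}
        amp_ids = {e[3] for e in cluster}
        if len(run_ids) < min_support:
            continue
        if require_both_amplifications and len(amps_present) > 1 and amp_ids != amps_present:
            continue
        sizes = [e[0] for e in cluster]
        heights = [e[1] for e in cluster]
        peaks.append(
            ConsensusPeak(
                size_bp=fmean(sizes),
                support=len(run_ids),
                mean_height_rfu=fmean(heights),
            )
        )
    return ConsensusProfile(sample_code, region, peaks)


def write_profiles(profiles: Iterable[ConsensusProfile], path) -> None:
    """Write consensus profiles as CSV (sample, region, size, support, height)."""
    import pandas as pd

    rows = [
        {
            "Sample": p.sample_code,
            "Region": p.intron_region,
            "Size": repr(peak.size_bp),
            "Support": peak.support,
            "MeanHeight": "" if peak.mean_height_rfu is None else repr(peak.mean_height_rfu),
        }
        for p in profiles
        for peak in p.peaks
    ]
    pd.DataFrame(
        rows, columns=["Sample", "Region", "Size", "Support", "MeanHeight"]
    ).to_csv(path, index=False)


def read_profiles(path) -> list[ConsensusProfile]:
    """Read consensus profiles written by :func:`write_profiles`."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[tuple[str, str], ConsensusProfile] = {}
    for _, row in df.iterrows():
        key = (str(row["Sample"]), str(row["Region"]))
        profile = out.setdefault(key, ConsensusProfile(key[0], key[1]))
        profile.peaks.append(
            ConsensusPeak(
                size_bp=float(row["Size"]),
                support=int(row["Support"]),
                mean_height_rfu=float(row["MeanHeight"]) if row["MeanHeight"] else None,
            )
        )
    return list(out.values())
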