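"""Reading and writing CE fragment-analysis data.

The entry point of a TBP experiment, once amplicons have been resolved by
capillary electrophoresis, is a *peak table*: one row per called peak, with a
sample code, a fractional fragment size in base pairs and a peak height in
relative fluorescence units (RFU).  Fragment-analysis software (GeneMapper and
friends) exports such tables as delimited text, with column names that vary by
instrument and locale; a :class:`PeakTableDialect` maps whatever headers a file
uses onto the fields this toolkit needs.

This module also implements the size-standard check that decides whether a
run's internal sizing ladder behaved: a sample peak is considered sizeable
only when the ladder fragments bracketing it were both recovered.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ColumnMappingError, CrossReferenceError, TBPKitError

__all__ = [
    "PeakRecord",
    "CERun",
    "SizeStandardDef",
    "SampleMetadata",
    "PeakTableDialect",
    "StandardVerdict",
    "normalize_region",
    "read_peak_table",
    "write_peak_table",
    "validate_size_standard",
    "read_metadata",
    "write_metadata",
    "check_sample_codes",
    "write_matrix",
    "read_matrix",
]

#: Accepted spellings for the two intron regions (and the combined assay),
#: including the thermal-cycle names used on TBP primer sheets.
_REGION_TOKENS = {
    "1": "first",
    "first": "first",
    "tbptd1i": "first",
    "2": "second",
    "second": "second",
    "tbptd2i": "second",
    "h": "h-tbp",
    "htbp": "h-tbp",
    "h-tbp": "h-tbp",
}


def normalize_region(token: str) -> str:
    """Normalize an intron-region label to ``first``/``second``/``h-tbp``."""
    key = str(token).strip().lower()
    try:
        return _REGION_TOKENS[key]
    except KeyError:
        raise TBPKitError(
            f"unknown intron-region token {token!r}; expected one of "
            f"{sorted(set(_REGION_TOKENS))}"
        ) from None


@dataclass(frozen=True)
class PeakRecord:
    """One called CE peak: fragment size (bp) and height (RFU)."""

    size_bp: float
    height_rfu: float
    area: float | None = None
    dye: str = "FAM"

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise TBPKitError(f"peak size must be positive, got {self.size_bp}")
        if self.height_rfu < 0:
            raise TBPKitError(f"peak height must be >= 0, got {self.height_rfu}")
        if self.area is not None and self.area < 0:
            raise TBPKitError(f"peak area must be >= 0, got {self.area}")


@dataclass
class CERun:
    """One capillary run: one sample, one intron region, one replicate.

    Every experimental sample is run four times (two independent
    amplifications x two dilutions); ``amplification_id`` and ``dilution_id``
    identify the replicate.  Peaks are kept sorted ascending by size.
    """

    sample_code: str
    intron_region: str
    amplification_id: str
    dilution_id: str
    peaks: list[PeakRecord] = field(default_factory=list)
    standard_ok: bool = True

    def __post_init__(self) -> None:
        self.intron_region = normalize_region(self.intron_region)
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (
            self.sample_code,
            self.intron_region,
            str(self.amplification_id),
            str(self.dilution_id),
        )


@dataclass(frozen=True)
class SizeStandardDef:
    """Definition of a co-injected sizing ladder (e.g. a 1200-bp LIZ ladder)."""

    name: str
    fragment_sizes_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.fragment_sizes_bp)
        if len(sizes) < 2:
            raise TBPKitError("a size standard needs at least 2 fragments")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise TBPKitError("size-standard fragments must be strictly ascending")
        object.__setattr__(self, "fragment_sizes_bp", sizes)


@dataclass
class SampleMetadata:
    """Accession-level metadata: code, Latin binomial, free-form group labels."""

    sample_code: str
    species: str
    groups: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PeakTableDialect:
    """Column mapping and parsing conventions for a peak-table export.

    Defaults match the toolkit's own CSV layout; every name, the delimiter
    and the decimal mark can be remapped to accommodate instrument exports.
    """

    sample: str = "Sample"
    region: str = "Region"
    amplification: str = "Amp"
    dilution: str = "Dilution"
    dye: str = "Dye"
    size: str = "Size"
    height: str = "Height"
    area: str = "Area"
    delimiter: str = ","
    decimal: str = "."


DEFAULT_DIALECT = PeakTableDialect()


def _require_columns(df: pd.DataFrame, dialect: PeakTableDialect) -> None:
    for role, name in (
        ("sample", dialect.sample),
        ("size", dialect.size),
        ("height", dialect.height),
    ):
        if name not in df.columns:
            raise ColumnMappingError(
                f"peak table is missing the required {role!r} column "
                f"(expected header {name!r}; found {list(df.columns)})"
            )


def read_peak_table(
    path: str | Path, dialect: PeakTableDialect = DEFAULT_DIALECT
) -> list[CERun]:
    """Read a peak-table export into one :class:`CERun` per replicate.

    Rows whose size or height cannot be parsed are reported through
    ``warnings`` with their row numbers, never silently dropped.  Duplicate
    rows for the same (sample, region, amplification, dilution, size) keep
    the highest-RFU entry, with a warning.
    """
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        dtype=str,
        skipinitialspace=True,
    )
    _require_columns(df, dialect)

    def col(name: str, default: str) -> pd.Series:
        if name in df.columns:
            return df[name].fillna(default)
        return pd.Series([default] * len(df), index=df.index)

    samples = df[dialect.sample].astype(str)
    regions = col(dialect.region, "first")
    amps = col(dialect.amplification, "1")
    dils = col(dialect.dilution, "1")
    dyes = col(dialect.dye, "FAM")
    areas = df[dialect.area] if dialect.area in df.columns else None

    bad_rows: list[tuple[int, str]] = []
    groups: dict[tuple[str, str, str, str], dict[float, PeakRecord]] = {}
    order: list[tuple[str, str, str, str]] = []
    for i in df.index:
        try:
            size = float(df.at[i, dialect.size])
            height = float(df.at[i, dialect.height])
            area_val = areas.at[i] if areas is not None else None
            area = float(area_val) if area_val not in (None, "") and pd.notna(area_val) else None
            peak = PeakRecord(size, height, area=area, dye=str(dyes.at[i]))
        except (TypeError, ValueError, TBPKitError) as exc:
            bad_rows.append((int(i) + 2, str(exc)))  # +2: header + 1-based
            continue
        key = (
            samples.at[i],
            normalize_region(regions.at[i]),
            str(amps.at[i]),
            str(dils.at[i]),
        )
        if key not in groups:
            groups[key] = {}
            order.append(key)
        bucket = groups[key]
        if size in bucket:
            warnings.warn(
                f"duplicate peak at {size} bp for {key}; keeping highest RFU",
                stacklevel=2,
            )
            if height <= bucket[size].height_rfu:
                continue
        bucket[size] = peak

    if bad_rows:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_rows[:10])
        warnings.warn(
            f"{len(bad_rows)} unparseable row(s) skipped in {path}: {detail}",
            stacklevel=2,
        )

    return [
        CERun(key[0], key[1], key[2], key[3], peaks=list(groups[key].values()))
        for key in order
    ]


def write_peak_table(
    runs: Iterable[CERun],
    path: str | Path,
    dialect: PeakTableDialect = DEFAULT_DIALECT,
) -> None:
    """Write runs back to a delimited peak table in the given dialect."""
    rows = []
    for run in runs:
        for p in run.peaks:
            rows.append(
                {
                    dialect.sample: run.sample_code,
                    dialect.region: run.intron_region,
                    dialect.amplification: run.amplification_id,
                    dialect.dilution: run.dilution_id,
                    dialect.dye: p.dye,
                    dialect.size: repr(p.size_bp),
                    dialect.height: repr(p.height_rfu),
                    dialect.area: "" if p.area is None else repr(p.area),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Size-standard validation
# ---------------------------------------------------------------------------


@dataclass
class StandardVerdict:
    """Outcome of checking observed ladder peaks against their definition.

    ``assignments`` maps each expected fragment length to the observed peak
    size matched to it (or None).  ``passed`` is the overall verdict;
    ``standard_ok`` additionally requires at least two matched fragments,
    without which no sample peak can be sized at all.
    """

    expected: tuple[float, ...]
    assignments: dict[float, float | None]
    passed: bool

    @property
    def n_matched(self) -> int:
        return sum(v is not None for v in self.assignments.values())

    @property
    def standard_ok(self) -> bool:
        return self.n_matched >= 2

    def sizeable(self, size_bp: float) -> bool:
        """True if both ladder fragments bracketing ``size_bp`` matched.

        Sizing interpolates between neighbouring ladder fragments, so a
        sample peak is trustworthy only when the preceding and subsequent
        expected fragments were both correctly recovered.
        """
        exp = self.expected
        if size_bp < exp[0] or size_bp > exp[-1]:
            return False
        i = bisect.bisect_left(exp, size_bp)
        # largest expected fragment <= size and smallest >= size (equal when
        # the peak sits exactly on a ladder fragment)
        above = exp[i]
        below = exp[i] if exp[i] == size_bp else exp[i - 1]
        return (
            self.assignments.get(below) is not None
            and self.assignments.get(above) is not None
        )


def validate_size_standard(
    observed: Sequence[PeakRecord],
    standard: SizeStandardDef,
    rel_height_min: float = 0.1,
    size_tol_bp: float = 0.5,
) -> StandardVerdict:
    """Match observed ladder peaks to the expected fragment list.

    Each expected fragment is matched to at most one observed peak within
    ``size_tol_bp``; observed peaks below ``rel_height_min`` times the median
    observed height are treated as noise and never matched.  The check passes
    only if every expected fragment found a match.  Shrinking the tolerance
    can only lose matches, so it can never turn a failing check into a pass.
    """
    sizes = [p.size_bp for p in observed]
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise TBPKitError("observed standard peaks must be sorted ascending")
    heights = [p.height_rfu for p in observed]
    if heights and rel_height_min > 0:
        med = sorted(heights)[len(heights) // 2]
        candidates = [p for p in observed if p.height_rfu >= rel_height_min * med]
    else:
        candidates = list(observed)

    used: set[int] = set()
    assignments: dict[float, float | None] = {}
    for frag in standard.fragment_sizes_bp:
        best_j, best_d = None, size_tol_bp
        for j, p in enumerate(candidates):
            if j in used:
                continue
            d = abs(p.size_bp - frag)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is None:
            assignments[frag] = None
        else:
            used.add(best_j)
            assignments[frag] = candidates[best_j].size_bp

    passed = all(v is not None for v in assignments.values())
    return StandardVerdict(standard.fragment_sizes_bp, assignments, passed)


# ---------------------------------------------------------------------------
# Metadata and matrix I/O
# ---------------------------------------------------------------------------

_CODE_HEADERS = ("code", "sample", "sample_code", "accession")
_SPECIES_HEADERS = ("species", "latin name", "latin_name", "latinname")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample-metadata CSV (accession code, species, group columns)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    lower = {c.lower().strip(): c for c in df.columns}
    code_col = next((lower[h] for h in _CODE_HEADERS if h in lower), None)
    species_col = next((lower[h] for h in _SPECIES_HEADERS if h in lower), None)
    if code_col is None:
        raise ColumnMappingError(
            f"metadata is missing a sample-code column (one of {_CODE_HEADERS})"
        )
    if species_col is None:
        raise ColumnMappingError(
            f"metadata is missing a species column (one of {_SPECIES_HEADERS})"
        )
    extra_cols = [c for c in df.columns if c not in (code_col, species_col)]
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        code = str(row[code_col]).strip()
        if code in seen:
            raise TBPKitError(f"duplicate sample code {code!r} in metadata")
        seen.add(code)
        out.append(
            SampleMetadata(
                sample_code=code,
                species=str(row[species_col]).strip(),
                groups={c: str(row[c]) for c in extra_cols},
            )
        )
    return out


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        {"Code": m.sample_code, "Species": m.species, **m.groups} for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def check_sample_codes(
    sample_codes: Iterable[str], metadata: Iterable[SampleMetadata]
) -> None:
    """Raise :class:`CrossReferenceError` for codes absent from the metadata."""
    known = {m.sample_code for m in metadata}
    unknown = sorted(set(sample_codes) - known)
    if unknown:
        raise CrossReferenceError(
            f"sample code(s) in peak data but not in metadata: {unknown}"
        )


def write_matrix(matrix, path: str | Path) -> None:
    """Write a binary marker matrix to CSV (samples x marker bins)."""
    matrix.to_frame().to_csv(path, index=True, index_label="Sample")


def read_matrix(path: str | Path):
    """Read a binary marker matrix written by :func:`write_matrix`."""
    from .binning import MarkerMatrix

    df = pd.read_csv(path, index_col="Sample")
    df.index = df.index.astype(str)
    return MarkerMatrix.from_frame(df)
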