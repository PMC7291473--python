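"""Exception hierarchy for tbpkit.

All toolkit errors derive from :class:`TBPKitError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class TBPKitError(ValueError):
    """Base class for all tbpkit errors."""


class ColumnMappingError(TBPKitError):
    """A required column is missing from a peak table or metadata file."""


class CrossReferenceError(TBPKitError):
    """Sample codes in peak data and metadata do not agree."""


class NoDataError(TBPKitError):
    """All runs of a sample/region were excluded; no consensus can be formed."""


class DegenerateProfileError(TBPKitError):
    """A sample has no scored markers, so pairwise dissimilarity is undefined."""


class ZeroVarianceError(TBPKitError):
    """A distance vector is constant, so a correlation is undefined."""
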