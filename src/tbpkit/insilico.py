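"""In-silico TBP: degenerate-primer site search and virtual amplicons.

TBP primers anneal to the conserved beta-tubulin exon sequences flanking the
two introns, so the assay can be simulated on any genomic or gene-family
sequence: find the primer footprints, pair a forward site with a downstream
reverse site, and the spanned segment (both footprints included — that is
what the capillary sizes, since the label rides on the forward primer) is a
virtual amplicon.  Three assay modes exist:

- ``first-intron``:  Fex1 + Rex1, spanning intron 1;
- ``second-intron``: Fin2 + Rin2, spanning intron 2;
- ``h-tbp``:         Fex1 + Rin2, spanning intron 1, exon 2 and intron 2.

All coordinates are 0-based, half-open, on the forward strand.  The primers
are degenerate (IUPAC codes); a primer position matches a target base when
their IUPAC base sets intersect, and an ``N`` in the *target* matches
nothing (it counts toward the mismatch budget).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import TBPKitError
from .qc import ConsensusPeak, ConsensusProfile

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "FEX1",
    "REX1",
    "FIN2",
    "RIN2",
    "PRIMER_PAIRS",
    "ExonModel",
    "PrimerSite",
    "VirtualAmplicon",
    "iupac_degeneracy",
    "expand_primer",
    "reverse_complement",
    "find_primer_sites",
    "predict_amplicons",
    "virtual_profile",
]

IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise TBPKitError(f"cannot complement symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC primer with its intended orientation."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.sequence.replace(" ", "").upper()
        for pos, sym in enumerate(seq):
            if sym not in IUPAC_SETS:
                raise TBPKitError(
                    f"primer {self.name}: illegal symbol {sym!r} at position {pos}"
                )
        if self.orientation not in ("forward", "reverse"):
            raise TBPKitError(f"orientation must be forward/reverse, got {self.orientation!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


# The four TBP primers, anchored in the conserved exon sequences bordering
# the two beta-tubulin introns.
FEX1 = DegeneratePrimer("Fex1", "AACTGGGCBAARGGNCAYTAYAC", "forward")
REX1 = DegeneratePrimer("Rex1", "ACCATRCAYTCRTCDGCRTTYTC", "reverse")
FIN2 = DegeneratePrimer("Fin2", "GARAAYGCHGAYGARTGYATG", "forward")
RIN2 = DegeneratePrimer("Rin2", "CRAAVCCBACCATGAARAARTGT", "reverse")

PRIMER_PAIRS: Mapping[str, tuple[DegeneratePrimer, DegeneratePrimer]] = {
    "first-intron": (FEX1, REX1),
    "second-intron": (FIN2, RIN2),
    "h-tbp": (FEX1, RIN2),
}


@dataclass(frozen=True)
class ExonModel:
    """Reference beta-tubulin exon lengths (bp) of the canonical plant gene."""

    first: int = 396
    second: int = 276
    third: int = 668

    def __post_init__(self) -> None:
        if min(self.first, self.second, self.third) <= 0:
            raise TBPKitError("exon lengths must be positive")

    @property
    def total_coding_bp(self) -> int:
        return self.first + self.second + self.third


def iupac_degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of concrete sequences a degenerate primer stands for."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    n = 1
    for pos, sym in enumerate(seq):
        try:
            n *= len(IUPAC_SETS[sym])
        except KeyError:
            raise TBPKitError(f"illegal IUPAC symbol {sym!r} at position {pos}") from None
    return n


def expand_primer(primer: DegeneratePrimer | str) -> list[str]:
    """All concrete expansions of a degenerate primer (use on small degeneracies)."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    out = [""]
    for sym in seq:
        bases = sorted(IUPAC_SETS[sym])
        out = [prefix + b for prefix in out for b in bases]
    return out


@dataclass(frozen=True)
class PrimerSite:
    """A primer footprint on the forward strand.

    ``strand`` is '+' when the primer (5'->3') reads along the forward
    strand, i.e. it extends rightward and acts as the left primer of a
    product, and '-' when its reverse complement lies on the forward strand
    (rightmost primer, extending leftward).
    """

    start: int
    end: int
    strand: str
    mismatches: int


def _match_at(seq: str, pos: int, pattern: Sequence[frozenset], budget: int) -> int | None:
    """Mismatch count of ``pattern`` at ``pos``, or None if above budget."""
    mism = 0
    for k, allowed in enumerate(pattern):
        base = seq[pos + k]
        # a target N is unknown sequence: it matches nothing (strict policy)
        if base == "N" or base not in allowed:
            mism += 1
            if mism > budget:
                return None
    return mism


def _pattern(seq: str) -> list[frozenset]:
    return [IUPAC_SETS[s] for s in seq]


def find_primer_sites(
    seq: str,
    primer: DegeneratePrimer,
    max_mismatch: int = 0,
    strands: str = "both",
) -> list[PrimerSite]:
    """All footprints of ``primer`` on a sequence, on one or both strands.

    The primer's intended orientation decides which match is the "expected"
    one: for a forward primer a direct match is reported as '+', for a
    reverse primer the reverse-complemented footprint is '-'.  With
    ``strands='both'`` the mirror configuration is searched too, so the
    caller sees every way the primer could prime on either strand;
    coordinates are always on the forward strand.
    """
    if max_mismatch < 0:
        raise TBPKitError("max_mismatch must be >= 0")
    if strands not in ("+", "-", "both"):
        raise TBPKitError(f"strands must be '+', '-' or 'both', got {strands!r}")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise TBPKitError(f"sequence contains non-nucleotide symbols: {sorted(bad)}")

    # '+' footprint: primer reads along the forward strand
    patterns = {
        "+": _pattern(primer.sequence),
        "-": _pattern(reverse_complement(primer.sequence)),
    }
    wanted = ("+", "-") if strands == "both" else (strands,)
    L = len(primer)
    sites: list[PrimerSite] = []
    for strand in wanted:
        pat = patterns[strand]
        for pos in range(len(s) - L + 1):
            mism = _match_at(s, pos, pat, max_mismatch)
            if mism is not None:
                sites.append(PrimerSite(pos, pos + L, strand, mism))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


@dataclass(frozen=True)
class VirtualAmplicon:
    """A predicted TBP product, coordinates 0-based half-open, forward strand."""

    seq_id: str
    mode: str
    start: int
    end: int
    strand: str
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def predict_amplicons(
    sequences: Mapping[str, str] | Iterable,
    mode: str,
    max_mismatch: int = 0,
    min_len: int = 50,
    max_len: int = 2000,
) -> list[VirtualAmplicon]:
    """Predict TBP amplicons for every sequence under one assay mode.

    ``sequences`` is a mapping id -> sequence or an iterable of Biopython
    ``SeqRecord`` objects.  For each sequence, every pairing of a left
    (forward-extending) site of the pair's forward primer with a downstream
    right site of the reverse primer yields an amplicon whose length spans
    both primer footprints; products outside [min_len, max_len] are
    discarded.  The mirror configuration (the product sitting on the
    reverse strand) is detected as well, so reverse-complementing the input
    leaves the predicted length multiset unchanged.  Zero amplicons is a
    legal result.
    """
    if mode not in PRIMER_PAIRS:
        raise TBPKitError(f"unknown mode {mode!r}; choose from {sorted(PRIMER_PAIRS)}")
    if not (0 < min_len <= max_len):
        raise TBPKitError(f"need 0 < min_len <= max_len, got {min_len}, {max_len}")
    fwd_primer, rev_primer = PRIMER_PAIRS[mode]

    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(rec.id, str(rec.seq)) for rec in sequences]

    out: list[VirtualAmplicon] = []
    for seq_id, seq in items:
        f_sites = find_primer_sites(seq, fwd_primer, max_mismatch, strands="both")
        r_sites = find_primer_sites(seq, rev_primer, max_mismatch, strands="both")
        # forward-strand products: forward primer as left ('+'), reverse as right ('-')
        for f in (x for x in f_sites if x.strand == "+"):
            for r in (x for x in r_sites if x.strand == "-"):
                if r.start < f.end:
                    continue
                length = r.end - f.start
                if min_len <= length <= max_len:
                    out.append(
                        VirtualAmplicon(
                            seq_id, mode, f.start, r.end, "+", f.mismatches, r.mismatches
                        )
                    )
        # reverse-strand products: the mirror image
        for r in (x for x in r_sites if x.strand == "+"):
            for f in (x for x in f_sites if x.strand == "-"):
                if f.start < r.end:
                    continue
                length = f.end - r.start
                if min_len <= length <= max_len:
                    out.append(
                        VirtualAmplicon(
                            seq_id, mode, r.start, f.end, "-", f.mismatches, r.mismatches
                        )
                    )
    out.sort(key=lambda a: (a.seq_id, a.start, a.end, a.strand))
    return out


def virtual_profile(
    amplicons: Sequence[VirtualAmplicon], sample_code: str
) -> ConsensusProfile:
    """Collapse predicted amplicons into a consensus-style peak list.

    One peak per distinct product length (exact integers; ties merged, with
    the number of co-migrating products recorded as the peak's support).
    The result feeds directly into marker binning alongside wet-lab
    profiles.
    """
    modes = {a.mode for a in amplicons}
    if len(modes) > 1:
        raise TBPKitError(f"amplicons mix assay modes {sorted(modes)}")
    region = {"first-intron": "first", "second-intron": "second", "h-tbp": "h-tbp"}[
        modes.pop()
    ] if modes else "first"
    lengths: dict[int, int] = {}
    for a in amplicons:
        lengths[a.length] = lengths.get(a.length, 0) + 1
    peaks = [
        ConsensusPeak(size_bp=float(size), support=count)
        for size, count in sorted(lengths.items())
    ]
    return ConsensusProfile(sample_code, region, peaks)
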