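"""Synthetic beta-tubulin gene families, species panels and noisy CE runs.

Three generators make the whole pipeline testable without wet-lab data:

- :func:`simulate_gene_family` writes gene sequences with the canonical
  exon1-intron1-exon2-intron2-exon3 architecture (exons 396/276/668 bp) and
  concrete expansions of the four TBP primers planted at the exon-intron
  boundaries, so in-silico amplification recovers the planted intron
  lengths exactly.

- :func:`simulate_panel` builds a multi-species accession panel as binary
  marker sets: each species has a founder marker set derived from a genus
  ancestor by per-marker turnover, and each accession perturbs its founder
  by per-marker dropout (plus the occasional private gain at the same
  rate).  With turnover above dropout, intra-specific dissimilarity sits
  below inter-specific dissimilarity by construction.

- :func:`simulate_ce_runs` turns true profiles into a noisy peak table with
  the real replicate structure (2 amplifications x 2 dilutions), Gaussian
  sizing jitter, log-normal peak heights and per-run peak dropout.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import TBPKitError
from .fragment_io import DEFAULT_DIALECT, PeakTableDialect, SampleMetadata
from .insilico import FEX1, FIN2, REX1, RIN2, ExonModel, expand_primer, reverse_complement
from .qc import ConsensusPeak, ConsensusProfile

__all__ = [
    "PanelSpec",
    "GeneFamilyTruth",
    "PanelTruth",
    "simulate_gene_family",
    "simulate_panel",
    "simulate_ce_runs",
]

_EXONS = ExonModel()

#: Offset (bp) of the conserved Rex1/Fin2 anchor motif within exon 2.
#: Reverse-complementing Rex1 yields the Fin2 motif extended by "GT", i.e.
#: the two exon-2 primers anneal at one and the same conserved site: Fin2
#: extends rightward toward intron 2, Rex1 leftward toward intron 1.  The
#: simulator therefore plants a single concrete Fin2 expansion followed by
#: "GT" at this fixed offset.
REX_FIN_MOTIF_OFFSET = 140


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _concrete(primer, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate primer, drawn uniformly."""
    from .insilico import IUPAC_SETS

    return "".join(rng.choice(sorted(IUPAC_SETS[s])) for s in primer.sequence)


@dataclass
class GeneFamilyTruth:
    """Planted structure of a simulated beta-tubulin gene family."""

    gene_ids: list[str]
    intron1_lengths: list[int]
    intron2_lengths: list[int]

    def expected_amplicon_lengths(self, mode: str) -> list[int]:
        """Product lengths in-silico TBP must recover, per assay mode.

        Both primer footprints are part of the product (the capillary sizes
        the full labelled fragment).  The first-intron product runs from the
        Fex1 footprint at the end of exon 1 to the Rex1 footprint on the
        shared exon-2 motif; the second-intron product from that same motif
        (Fin2) to the Rin2 footprint at the start of exon 3; h-TBP spans
        intron1 + exon2 + intron2 plus the two outer footprints.
        """
        if mode == "first-intron":
            pad = len(FEX1) + REX_FIN_MOTIF_OFFSET + len(REX1)
            return sorted(i + pad for i in self.intron1_lengths)
        if mode == "second-intron":
            pad = (_EXONS.second - REX_FIN_MOTIF_OFFSET) + len(RIN2)
            return sorted(i + pad for i in self.intron2_lengths)
        if mode == "h-tbp":
            pad = len(FEX1) + len(RIN2) + _EXONS.second
            return sorted(
                i1 + i2 + pad
                for i1, i2 in zip(self.intron1_lengths, self.intron2_lengths)
            )
        raise TBPKitError(f"unknown mode {mode!r}")


def _default_intron_sampler(lo: int = 60, hi: int = 600, step: int = 3):
    """Sample intron lengths without replacement on a >=3 bp-spaced grid.

    The spacing keeps planted lengths unambiguous at the default 1-bp
    binning tolerance even after sizing jitter.
    """

    def sampler(rng: np.random.Generator, n: int) -> list[int]:
        grid = np.arange(lo, hi + 1, step)
        if n > grid.size:
            raise TBPKitError(f"cannot draw {n} distinct intron lengths from grid of {grid.size}")
        return [int(x) for x in rng.choice(grid, size=n, replace=False)]

    return sampler


def simulate_gene_family(
    n_genes: int,
    intron_len_sampler: Callable[[np.random.Generator, int], Sequence[int]] | None = None,
    seed: int | None = None,
    prefix: str = "btub",
) -> tuple[list[SeqRecord], GeneFamilyTruth]:
    """Generate a beta-tubulin gene family with planted intron lengths.

    Each gene is exon1(396) . intron1 . exon2(276) . intron2 . exon3(668)
    with a concrete expansion of Fex1 ending exon 1, the shared Rex1/Fin2
    anchor motif (a Fin2 expansion followed by "GT") at a fixed offset
    inside exon 2, and the reverse complement of a Rin2 expansion starting
    exon 3; everything else is uniform random ACGT.  Byte-identical output
    under a fixed seed.
    """
    if n_genes < 1:
        raise TBPKitError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    sampler = intron_len_sampler or _default_intron_sampler()
    i1 = [int(x) for x in sampler(rng, n_genes)]
    i2 = [int(x) for x in sampler(rng, n_genes)]
    for L in (*i1, *i2):
        if not (50 <= L <= 1800):
            raise TBPKitError(f"sampled intron length {L} outside [50, 1800]")

    records: list[SeqRecord] = []
    ids: list[str] = []
    for g in range(n_genes):
        fex = _concrete(FEX1, rng)
        motif = _concrete(FIN2, rng) + "GT"  # doubles as the Rex1 footprint
        rin_rc = reverse_complement(_concrete(RIN2, rng))
        exon1 = _random_seq(rng, _EXONS.first - len(fex)) + fex
        exon2 = (
            _random_seq(rng, REX_FIN_MOTIF_OFFSET)
            + motif
            + _random_seq(rng, _EXONS.second - REX_FIN_MOTIF_OFFSET - len(motif))
        )
        exon3 = rin_rc + _random_seq(rng, _EXONS.third - len(rin_rc))
        seq = (
            exon1
            + _random_seq(rng, i1[g])
            + exon2
            + _random_seq(rng, i2[g])
            + exon3
        )
        gene_id = f"{prefix}{g + 1:02d}"
        ids.append(gene_id)
        records.append(
            SeqRecord(
                Seq(seq),
                id=gene_id,
                description=f"synthetic beta-tubulin gene, intron1={i1[g]} intron2={i2[g]}",
            )
        )
    return records, GeneFamilyTruth(ids, i1, i2)


# ---------------------------------------------------------------------------
# Species panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """Study design of a synthetic accession panel.

    Gene counts per genome mirror real TBP panels: roughly 8-10 amplified
    beta-tubulin members per intron region in diploids and 15-26 in
    tetraploids, so ``genes_tetraploid`` must exceed ``genes_diploid``.
    ``dropout`` controls intra-specific marker loss/gain per accession;
    ``turnover`` controls per-marker replacement between a species founder
    and the genus ancestor, so turnover > dropout yields the expected
    intra < inter dissimilarity structure.
    """

    n_species: int = 3
    accessions_per_species: int = 4
    ploidies: tuple[int, ...] | None = None  # per species; default all diploid
    genes_diploid: int = 9
    genes_tetraploid: int = 20
    size_range_bp: tuple[float, float] = (100.0, 1000.0)
    grid_step_bp: float = 4.0
    dropout: float = 0.05
    turnover: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.accessions_per_species < 1:
            raise TBPKitError("species and accession counts must be positive")
        if not (0 <= self.dropout <= 1 and 0 <= self.turnover <= 1):
            raise TBPKitError("dropout and turnover must be probabilities in [0, 1]")
        if self.genes_tetraploid <= self.genes_diploid:
            raise TBPKitError("tetraploid gene count must exceed the diploid count")
        if self.grid_step_bp < 3.0:
            raise TBPKitError("grid_step_bp below 3 bp makes planted markers ambiguous")
        if self.ploidies is None:
            self.ploidies = (2,) * self.n_species
        if len(self.ploidies) != self.n_species:
            raise TBPKitError("ploidies must list one value per species")
        if any(p not in (2, 4) for p in self.ploidies):
            raise TBPKitError("supported ploidies are 2 and 4")

    def genes_for(self, species_index: int) -> int:
        return self.genes_diploid if self.ploidies[species_index] == 2 else self.genes_tetraploid


@dataclass
class PanelTruth:
    """Ground truth of a simulated panel, consistent with its outputs."""

    species: dict[str, str]
    marker_sets: dict[str, dict[str, tuple[float, ...]]]
    founder_sets: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "species": self.species,
            "marker_sets": {
                s: {r: list(v) for r, v in regions.items()}
                for s, regions in self.marker_sets.items()
            },
            "founder_sets": {
                s: {r: list(v) for r, v in regions.items()}
                for s, regions in self.founder_sets.items()
            },
        }


REGIONS = ("first", "second")


def simulate_panel(
    spec: PanelSpec,
) -> tuple[list[ConsensusProfile], list[SampleMetadata], PanelTruth]:
    """Simulate true (noise-free) marker profiles for a species panel.

    Marker sizes live on a spaced grid and are allocated without
    replacement, so two distinct markers never collide in a 1-bp binning.
    Returns per-sample/per-region profiles, accession metadata and the
    ground truth (species assignment and exact marker sets).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range_bp
    reserve = {
        region: [float(x) for x in rng.permutation(np.arange(lo, hi + 1e-9, spec.grid_step_bp))]
        for region in REGIONS
    }

    def draw(region: str) -> float:
        try:
            return reserve[region].pop()
        except IndexError:
            raise TBPKitError(
                "marker size grid exhausted; widen size_range_bp or grid_step_bp"
            ) from None

    max_genes = max(spec.genes_for(i) for i in range(spec.n_species))
    ancestor = {region: [draw(region) for _ in range(max_genes)] for region in REGIONS}

    founders: dict[str, dict[str, tuple[float, ...]]] = {}
    species_names = [f"Species {chr(ord('A') + i)}" for i in range(spec.n_species)]
    for i, name in enumerate(species_names):
        founders[name] = {}
        for region in REGIONS:
            markers = []
            for m in ancestor[region][: spec.genes_for(i)]:
                if rng.random() < spec.turnover:
                    markers.append(draw(region))  # lineage-specific length
                else:
                    markers.append(m)
            founders[name][region] = tuple(sorted(markers))

    profiles: list[ConsensusProfile] = []
    metadata: list[SampleMetadata] = []
    species_of: dict[str, str] = {}
    marker_sets: dict[str, dict[str, tuple[float, ...]]] = {}
    for i, name in enumerate(species_names):
        for j in range(spec.accessions_per_species):
            code = f"sp{i + 1:02d}a{j + 1:02d}"
            species_of[code] = name
            metadata.append(
                SampleMetadata(
                    code,
                    name,
                    groups={"Ploidy": str(spec.ploidies[i]), "Form": "synthetic"},
                )
            )
            marker_sets[code] = {}
            for region in REGIONS:
                kept = [m for m in founders[name][region] if rng.random() >= spec.dropout]
                if rng.random() < spec.dropout:
                    kept.append(draw(region))  # rare accession-private gain
                if not kept:  # a profile must retain at least one marker
                    kept.append(founders[name][region][0])
                sizes = tuple(sorted(kept))
                marker_sets[code][region] = sizes
                profiles.append(
                    ConsensusProfile(
                        code,
                        region,
                        [ConsensusPeak(s, support=4, mean_height_rfu=2000.0) for s in sizes],
                    )
                )
    truth = PanelTruth(species_of, marker_sets, founders)
    return profiles, metadata, truth


# ---------------------------------------------------------------------------
# Noisy CE runs
# ---------------------------------------------------------------------------


def simulate_ce_runs(
    profiles: Sequence[ConsensusProfile],
    jitter_sd_bp: float = 0.3,
    height_mu_log: float = math.log(2000.0),
    height_sigma_log: float = 0.8,
    dropout_per_run: float = 0.02,
    out_of_scale_prob: float = 0.0,
    seed: int | None = None,
    path: str | Path | None = None,
    dialect: PeakTableDialect = DEFAULT_DIALECT,
) -> pd.DataFrame:
    """Emit a noisy CE peak table for the four replicate runs of each profile.

    Each sample/region is written as 2 amplifications x 2 dilutions.  Every
    true peak is independently dropped with ``dropout_per_run``, its size
    jittered by Normal(0, jitter_sd_bp) and its height drawn log-normally
    (clipped to [1, 40000] RFU — above the 32,000 RFU scoring ceiling on
    purpose, so saturation can occur).  With ``out_of_scale_prob`` a run is
    made saturated by pushing one of its peaks above 32,000 RFU, which the
    QC step must then exclude.  If ``path`` is given the table is also
    written as CSV in the peak-table dialect.
    """
    if jitter_sd_bp < 0 or not (0 <= dropout_per_run <= 1) or not (0 <= out_of_scale_prob <= 1):
        raise TBPKitError("invalid noise parameters")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for profile in profiles:
        for amp in ("1", "2"):
            for dil in ("1", "2"):
                run_rows: list[dict] = []
                for peak in profile.peaks:
                    if rng.random() < dropout_per_run:
                        continue
                    size = peak.size_bp + (rng.normal(0.0, jitter_sd_bp) if jitter_sd_bp else 0.0)
                    height = float(
                        np.clip(rng.lognormal(height_mu_log, height_sigma_log), 1.0, 40000.0)
                    )
                    run_rows.append(
                        {
                            dialect.sample: profile.sample_code,
                            dialect.region: profile.intron_region,
                            dialect.amplification: amp,
                            dialect.dilution: dil,
                            dialect.dye: "FAM",
                            dialect.size: round(size, 4),
                            dialect.height: round(height, 1),
                            dialect.area: "",
                        }
                    )
                if run_rows and rng.random() < out_of_scale_prob:
                    victim = rng.integers(0, len(run_rows))
                    run_rows[victim][dialect.height] = round(
                        float(rng.uniform(32001.0, 40000.0)), 1
                    )
                rows.extend(run_rows)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep=dialect.delimiter, index=False)
    return df
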