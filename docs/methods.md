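# Methods

This note documents the models, conventions and numerical choices behind
`tbpkit`, in the spirit of the methods documentation of statistical
genetics packages: what each stage computes, which parameters matter, and
what the synthetic-data validation does and does not demonstrate.

## The assay being modelled

TBP (tubulin-based polymorphism) profiles a genome through the intron
length polymorphism of its β-tubulin gene family.  Plant β-tubulin genes
share a conserved three-exon architecture (reference exon lengths 396, 276
and 668 bp — a 1340-bp coding sequence) with two introns at fixed
positions.  Degenerate primers anchored in the conserved exon sequences
amplify, in one reaction, the corresponding intron from every family
member; the products are sized on a capillary sequencer against a
co-injected ladder.  A sample's profile is therefore a list of peaks, each
a fragment size in base pairs (fractional — CE sizing is sub-integer) and
a height in relative fluorescence units (RFU).

Two primer pairs exist: Fex1/Rex1 for the first intron and Fin2/Rin2 for
the second; Fex1/Rin2 amplifies the combined first-intron–exon-2–second-
intron fragment (h-TBP).  A structural fact the toolkit relies on: the
reverse complement of Rex1 is the Fin2 motif extended by `GT`, i.e. both
exon-2 primers anneal to one and the same conserved site, Fin2 extending
toward intron 2 and Rex1 back toward intron 1.  The in-silico module treats
an amplicon as spanning both primer footprints, because that is the full
labelled fragment the capillary sizes.

## Pipeline stages and their parameters

**Size-standard validation.**  Expected ladder fragments are greedily
matched to the nearest observed peak within `size_tol_bp` (default 0.5 bp),
ignoring observed peaks below `rel_height_min` (default 0.1) times the
median observed height.  A sample peak is *sizeable* only if the ladder
fragments bracketing it both matched, since sizing interpolates between
neighbouring ladder points.  The two defaults are this package's own
conventions; fragment-analysis software does an equivalent check but does
not document its thresholds.

**Height filtering.**  Peaks are recorded only if their height *strictly
exceeds* `min_rfu` (default 50 RFU — "exceeds" is read literally, so a
50.0-RFU peak is dropped).  Any peak above `max_rfu` (default 32,000 RFU)
means detector saturation, and the whole run is excluded rather than
trimmed: a saturated trace distorts neighbouring calls.

**Replicate consolidation.**  Each sample/region is measured by four runs
(2 amplifications × 2 dilutions).  Peaks pooled across the surviving runs
are clustered by single linkage with a gap cut at `size_tol_bp` (default
1.0 bp, comfortably above sub-bp CE repeatability).  A cluster becomes a
consensus peak only if it contains peaks from at least `min_support`
(default 2) distinct runs *and*, when both amplifications have surviving
runs, from both amplifications — reproducibility across independent
amplifications is the purpose of the replicate design.  How exactly the
four runs should be merged is not standardised anywhere; this support rule
is an explicit, overridable convention of the package.  If a run is
excluded by QC the sample proceeds with the remaining runs.  With
`min_support=2` a sample/region reduced to a single surviving run yields
an empty consensus; the caller is warned rather than given unreplicated
peaks.

**Marker binning.**  All consensus sizes of one region, across samples,
are sorted ascending and cut into bins wherever the gap to the previous
size exceeds `gap_tol_bp` (default 1.0 bp).  This is single-linkage
clustering with a distance cut, verified in the tests against an
exhaustive single-linkage oracle.  Chaining is the known failure mode — a
dense run of sizes can merge into one wide bin — so any bin spanning more
than twice the tolerance triggers a warning.  If one sample contributes
two peaks to a bin it still scores a single presence (the matrix is binary
by definition) with a collision warning.  Samples missing one region are
excluded from combined-region analyses by default rather than imputed.

**Whittaker dissimilarity.**  `βW = S/ᾱ − 1`, with `S` the union size of
the pair's marker sets and `ᾱ` their mean richness; algebraically
`(b+c)/(2a+b+c)` for `a` shared and `b`, `c` private markers.  On binary
data this equals the Sørensen dissimilarity — worth knowing when comparing
with other software.  It is undefined for an all-zero profile, which is
treated as an error rather than silently scored.

**Shannon index.**  `H = −Σ pᵢ ln pᵢ` requires choosing what `pᵢ` is.  The
implemented convention, `presence-frequency`, takes marker *i*'s share of
all marker presences within the group.  Published TBP and AFLP studies
rarely state their convention and values are not comparable across
conventions, so the convention is a *required* keyword argument — there is
deliberately no default.

**Barcoding gap.**  Pairwise dissimilarities are split by species label
into intra- and inter-specific sets.  The overlap is the fraction of all
observations (both sets pooled) inside the closed interval
`[min(inter), max(intra)]`, zero when the interval is empty.  This is an
interval-based definition; histogram-based overlap measures would give
different numbers.

**PCA.**  Eigendecomposition of the covariance matrix of the 0/1 markers
(column-mean-centred, unscaled), the convention of classical multivariate
packages for dominant marker data.  Percent variance is
eigenvalue/total × 100 and sums to 100 over all components; scores are
defined up to the usual per-component sign flip.  All-identical rows give
zero total variance and a `degenerate` flag instead of an error.

**Neighbor joining.**  Implemented in-package (Saitou–Nei, standard
Q-criterion) so that two things are fixed conventions rather than
library-dependent behaviour: ties in the Q minimisation break toward the
lowest index pair, and a negative branch length is clamped to zero with
the deficit moved to the sister branch, preserving the joined pair's path
length.  For additive matrices the reconstruction is exact; the tests
verify machine-precision round trips on random trees and topological
agreement with an independent NJ implementation.

**Bootstrap.**  Marker columns are the exchangeable unit of a binary
marker matrix, so replicates resample columns with replacement (same
column count), recompute Whittaker distances and the NJ tree, and support
of an internal edge is the percentage of replicates containing the same
leaf bipartition (1000 replicates by default).  Samples are put in sorted
order before any computation so supports cannot depend on input row order.
A replicate that zeroes out a sample's entire profile is redrawn and
counted.

**Matrix correlations.**  The cophenetic correlation is the Pearson
correlation between input distances and tree path lengths over all pairs.
The same quantity between two independently estimated distance matrices is
computed Mantel-style, with significance from permuting the sample labels
of one matrix (one-sided, greater; add-one p-value).  Both routes are
provided because "cophenetic correlation" is used in the literature for
either; results are tagged with which was computed.

## In-silico TBP

Primer sites are found by IUPAC set intersection: a primer position
matches a target base when their base sets intersect; an `N` in the target
matches nothing and consumes mismatch budget (strict policy).  The default
mismatch budget is 0 — the primers are already degenerate, and tolerance
is exposed but off by default.  Coordinates are 0-based, half-open, on the
forward strand throughout.  Products are enumerated for every left-site ×
downstream-right-site pairing within `[min_len, max_len]` (defaults
50–2000 bp), on both strands, so reverse-complementing the input leaves
the predicted length multiset unchanged.  No thermodynamics (Tm, 3'-end
stability) is modelled; the degenerate-set match is the annealing model.

## What the synthetic data emulates — and what it does not

`simulate_gene_family` plants the real gene architecture (exon lengths,
primer sites at their boundaries, the shared exon-2 motif) around introns
drawn without replacement from a ≥3-bp-spaced grid, so ground truth stays
unambiguous at the default 1-bp binning tolerance.  `simulate_panel`
models a panel as: a genus-ancestor marker set per region; species
founders derived by per-marker turnover (default 0.5); accessions derived
from founders by per-marker dropout (default 0.05, with an occasional
private gain at the same rate).  Diploid genomes carry 9 markers per
region and tetraploids 20, mirroring the peak counts seen in real diploid
vs. allotetraploid legume panels.  The default panel is 3 species × 4
accessions.  `simulate_ce_runs` renders profiles as the four replicate
runs with Gaussian sizing jitter (SD 0.3 bp), log-normal heights
(median 2000 RFU, σ = 0.8 on the log scale, clipped to [1, 40000] so
saturation is possible), and 2% per-run peak dropout.

Real CE-TBP data differ in ways the generator does not model: peak heights
correlate with fragment length and template quality, sizing error grows
with length, markers are not independent (they ride on gene trees),
heterozygosity produces sub-stoichiometric peaks, and co-migrating
non-homologous fragments can collide in one bin.  Passing the recovery
tests therefore shows the *pipeline machinery* is correct — thresholds,
consolidation, binning, diversity and tree code do what they claim — not
that the assay itself resolves any particular real taxon pair.

## Problem sizes and numerical tolerances

The validation suite runs the full pipeline on the default 12-accession
panel with 1000 bootstrap replicates and 999 Mantel permutations, checks
Whittaker values by exhaustive enumeration of all binary pairs up to 8
markers, NJ on 50 random additive trees of 4–12 taxa (round trip at
1e-10 relative tolerance), PCA against an external eigensolver on random
6 × 10 matrices (1e-8 absolute on percent variance), binning against
exhaustive single linkage for up to 15 peaks, and the degenerate matcher
against brute-force expansion search for primers of degeneracy ≤ 96.
These sizes keep the whole suite under a minute while covering every
estimator with an independent oracle.

## Known limitations

- Dominant (presence/absence) markers only: no codominant allele calling,
  no dosage from peak heights, no ploidy inference.
- Consolidation and binning tolerances are global, not size-dependent.
- The barcoding-gap overlap is interval-based and sensitive to single
  outlier pairs by construction.
- In-silico prediction ignores PCR competition and amplification bias; a
  predicted product is not a guaranteed wet-lab peak.
- Proprietary trace files (.fsa/.hid) are out of scope; ingestion starts
  from exported peak tables.
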