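# tbpkit

Tubulin-Based Polymorphism (TBP) is a DNA fingerprinting assay for plants:
degenerate primers anchored in the conserved exons of the β-tubulin gene
family amplify the two introns of every family member, the fluorescently
labelled products are sized by capillary electrophoresis (CE), and the
multiset of fragment lengths — typically 5–25 peaks per sample and intron
region — is a genome profile that discriminates taxa from genera down to
cultivars and ecotypes.  The assay needs no prior sequence information, which
makes it attractive for crop wild relatives, orphan crops and germplasm
collections.

`tbpkit` implements the complete computational side of the assay for people
who run (or simulate) CE-TBP experiments:

- **Ingestion & QC** — parse fragment-analysis peak tables (configurable
  column dialects), validate runs against the co-injected size standard,
  apply the peak-height thresholds (record only peaks > 50 RFU; discard any
  run with a peak > 32,000 RFU as saturated).
- **Replicate consolidation** — each sample is measured by four runs
  (2 independent amplifications × 2 dilutions); peaks must be reproducible
  across runs, and across both amplifications, to enter the consensus
  profile.
- **Marker scoring** — pooled consensus sizes are sorted ascending and cut
  into bins wherever the gap exceeds a tolerance; each bin is a dominant
  marker scored 1/0 per sample (the binary matrix).
- **Diversity** — pairwise Whittaker β-diversity
  `βW = S/ᾱ − 1 = (b + c)/(2a + b + c)` (a shared, b/c private markers),
  Shannon index `H = −Σ pᵢ ln pᵢ`, and the barcoding-gap analysis: the
  overlap between intra- and inter-specific distance distributions.
- **Ordination & trees** — PCA on the covariance matrix of the binary
  markers; neighbor-joining trees with bootstrap support from resampling
  marker columns (1000 replicates by default); cophenetic and Mantel matrix
  correlations.
- **In-silico TBP** — predict virtual amplicons from any FASTA using the
  four degenerate primers (Fex1/Rex1 for intron 1, Fin2/Rin2 for intron 2,
  Fex1/Rin2 for the combined h-TBP assay).
- **Synthetic data** — generate β-tubulin gene families with planted intron
  lengths, multi-species accession panels with controlled intra/inter
  divergence, and noisy CE peak tables, so every stage is testable end to
  end without wet-lab data.

## Worked example

Simulate a 3-species × 4-accession panel, render it as noisy CE peak tables,
and push it through the full pipeline:

```python
from pathlib import Path
import tempfile
from tbpkit import (PanelSpec, simulate_panel, simulate_ce_runs, read_peak_table,
                    filter_run, consolidate, combine_regions, dissimilarity_matrix,
                    partition_intra_inter, bootstrap_support, polymorphic_count)
from tbpkit.binning import bin_markers

spec = PanelSpec(seed=1)                      # 3 species x 4 accessions
profiles, metadata, truth = simulate_panel(spec)
with tempfile.TemporaryDirectory() as tmp:
    peaks = Path(tmp) / "peaks.csv"
    simulate_ce_runs(profiles, seed=2, path=peaks)
    runs = read_peak_table(peaks)

groups = {}
for run in runs:
    v = filter_run(run)                       # 50 / 32,000 RFU thresholds
    if not v.excluded:
        groups.setdefault((run.sample_code, run.intron_region), []).append(v.run)
consensus = [consolidate(g) for g in groups.values()]

per_region = {r: bin_markers([p for p in consensus if p.intron_region == r])[1]
              for r in ("first", "second")}
matrix = combine_regions(per_region["first"], per_region["second"])
n_poly, pct = polymorphic_count(matrix)
print(f"{len(matrix.bins)} markers ({n_poly} polymorphic, {pct:.1f}%)")

gap = partition_intra_inter(dissimilarity_matrix(matrix), metadata)
print(f"intra-specific Whittaker range: {gap.intra_range[0]:.3f}-{gap.intra_range[1]:.3f}")
print(f"inter-specific Whittaker range: {gap.inter_range[0]:.3f}-{gap.inter_range[1]:.3f}")
print(f"barcoding-gap overlap fraction: {gap.overlap_fraction:.3f}")

tree = bootstrap_support(matrix, n_reps=1000, seed=3)
for sp in sorted(set(truth.species.values())):
    clade = [c for c, s in truth.species.items() if s == sp]
    print(f"{sp}: bootstrap support {tree.support_for(clade):.1f}%")
```

Output:

```
46 markers (46 polymorphic, 100.0%)
intra-specific Whittaker range: 0.000-0.091
inter-specific Whittaker range: 0.765-0.943
barcoding-gap overlap fraction: 0.000
Species A: bootstrap support 100.0%
Species B: bootstrap support 100.0%
Species C: bootstrap support 100.0%
```

The 12 accessions yield 46 binned markers, all polymorphic.  Within-species
dissimilarities (≤ 0.091) sit far below between-species ones (≥ 0.765), so
the intra/inter distributions do not overlap — a clean barcoding gap — and
every species comes back as a fully supported clade in the bootstrap NJ
tree.

The same pipeline is available as a CLI of restartable, file-based stages:

```sh
tbpkit simulate --out-dir work --seed 7
tbpkit ingest work/peaks.csv --out work/runs.json
tbpkit filter work/runs.json --out work/filtered.json
tbpkit consolidate work/filtered.json --out work/profiles.csv
tbpkit bin work/profiles.csv --out work/matrix.csv
tbpkit report work --out work/report.json --seed 7
```

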