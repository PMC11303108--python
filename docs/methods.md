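# Methods

## Problem and overall procedure

`tfgate` identifies candidate *direct* transcriptional targets of a
transcription factor (TF) in a specific cell type by intersecting three
independent lines of evidence, mirroring the design used to nominate c-Fos
targets in rod photoreceptors of the oxygen-induced retinopathy (OIR) mouse
model:

1. **Chromatin-state gate.** From per-antibody peak calls (TF binding,
   H3K27ac, H3K4me3, H3K27me3), a gene passes the *active-promoter gate* in
   a condition when at least one peak of **every** activation mark (TF,
   H3K27ac, H3K4me3) overlaps its promoter window and **no** H3K27me3 peak
   does. The promoter window is the closed interval ±w bp around the
   strand-aware TSS (default w = 1000, i.e. ±1.0 kb; 2w+1 bp, left-clipped
   at the chromosome start). Overlap means ≥ 1 bp.
2. **Condition exclusivity.** Genes are kept only if they pass the gate in
   the focal (disease) condition and in *no other* condition in the ledger
   — for a two-condition ledger this is the set difference vs the control.
3. **Expression filter.** Genes must be detected (raw count > 0) in at
   least `expressed_min_fraction` (default 1%) of the focal cells.
4. **Single-cell DEG stage.** Within the cell type of interest in the focal
   condition, cells are split into TF⁺ (raw TF count ≥ 1) and TF⁻ groups
   and each gene is tested with a two-sided Mann-Whitney U test; genes with
   BH q < 0.05 and |log2FC| ≥ 0.25 are DEGs. Candidates are the
   intersection of steps 2–4.

The expression filter sits between gate exclusivity and the DEG
intersection; the report also records the cardinality of the alternative
ordering (expression applied before exclusion) since the original narrative
leaves the order ambiguous.

## Statistical details

- **Normalization**: counts per 10,000 (CP10K) per cell, log1p for scoring
  and rank tests. Cells with zero totals are excluded with a warning.
- **Cell typing**: the per-type score is the mean log1p(CP10K) over that
  type's marker genes; a cell gets the argmax label unless the margin to
  the runner-up is < 0.25 (ties therefore unassigned). This replaces
  clustering+embedding approaches deliberately: the sole purpose here is to
  isolate one cell type deterministically and testably.
- **Mann-Whitney U**: tie-corrected normal approximation with continuity
  correction (scipy) in general; when both groups have ≤ 8 cells the exact
  two-sided p is computed by full enumeration of group labelings (tie-safe,
  deviation measured as |U − n₁n₂/2|). Genes constant across both groups
  get p = 1 by convention.
- **Fold change**: log2 of the ratio of group means on the CP10K scale with
  a pseudocount of 1 added to both means.
- **Multiple testing**: Benjamini-Hochberg step-up q-values
  (statsmodels); the test suite checks them against an independent
  from-the-definition implementation.

## Promoter motif and reporter-construct engine

The AP-1 complex binds the TRE consensus TGA(C/G)TCA. The two admissible
7-mers, TGACTCA and TGAGTCA, are mutual reverse complements, so one forward
scan covers both strands; a site is reported once (strand "+" for the
TGACTCA reading). Half sites are the invariant 4-mer TGAC (reverse reading
GTCA); occurrences inside a full TRE are flagged *embedded*. N never
matches. The half-site word is configurable in principle; TGAC was chosen
because it is the invariant half of the consensus and contains the
single-nucleotide mutation (TGAC→TTAC) known to abolish AP-1-driven
activity.

Reporter constructs are promoter fragments in TSS-relative coordinates
(negative upstream, half-open intervals after mapping) with an activity
label. The essential region is

    (∩ retained intervals over active constructs) −
    (∪ retained intervals over inactive constructs)

as a sorted disjoint interval set, computed with exact integer interval
algebra (checked against bp-resolution boolean masks in tests). A construct
is predicted active iff it retains the entire essential region; this
prediction provably reproduces the input labels whenever the inferred
region is non-empty. With no inactive construct the intersection of actives
is returned with a warning — it is then only an upper bound. The canonical
five-construct deletion series over the 1.1 kb promoter (intact plus four
progressive deletions) isolates the proximal 0.3 kb as essential.

## Synthetic data generator

The generator emulates the study's inputs at desk scale so every stage can
be scored against planted ground truth:

- **Annotation**: 400 genes on 3 × 1.5 Mb chromosomes, random strand and
  length (1–5 kb), laid out on a per-chromosome grid with jitter. The
  layout keeps ≥ 3 kb between adjacent genes so a planted promoter peak
  can never overlap a neighboring gene's ±1 kb window (gate truth would
  otherwise leak between neighbors by construction).
- **Peaks**: planted 400 bp peaks centered on the TSS (±100 bp jitter) per
  gene class (table in the module docstring: disease-only targets,
  both-condition actives, disease-only non-DEGs, control-only, repressed,
  partial-mark), plus uniform Poisson background peaks at 5 per Mbp per
  mark and condition, for all five antibodies (IgG carries background
  only). Each decoy class falsifies exactly one clause of the gate.
- **Counts**: negative binomial with gene-level baseline means ~
  Gamma(2, 2.0) and dispersion r = 2 (var = m + m²/r); 350 cells per
  condition × timepoint; cell types drawn at rod:bipolar:Müller =
  0.7:0.2:0.1; 5 marker genes per type boosted 20× in their own type. The
  TF gene is bimodal in disease rods (40% positive at mean 3, the rest at
  0) and near-silent elsewhere (mean 0.05). 5% of genes are planted DEGs
  (the 10 direct targets plus extras) with a 4× mean shift in TF⁺ disease
  rods at the focal timepoint only.
- **Promoters**: one 1.1 kb sequence per direct target with 0–3 planted
  full TREs and 0–4 free-standing half sites (≥ 8 bp apart); the random
  background is scrubbed of accidental motif words by iteratively mutating
  one base of each accidental match outside all planted footprints
  (guarded at 200 iterations), so scans recover exactly the planted sites.

All randomness flows through per-component `numpy` Generator streams seeded
as `[seed, component]`, so every output is byte-deterministic given the
config.

### Calibration of the count model

Per-cell normalization couples genes: boosting planted DEGs in TF⁺ cells
inflates TF⁺ library sizes, which imparts a systematic *negative* log2FC on
all unchanged genes (a compositional artifact familiar from real scRNA-seq
normalization). The defaults were therefore chosen by a power/composition
analysis: the background library (~1,700 counts/cell) dominates the
planted-gene mass, so even at an 8× effect the planted boost is ≤ 4% of the
library (systematic |log2FC| < 0.07, far below the 0.25 DEG threshold),
while the planted baseline of 0.5 counts/cell gives ≈ 6σ TF⁺/TF⁻ separation
per DEG at the default 4× effect. With ~100 vs ~150 cells this yields
per-gene DEG sensitivity ≳ 99.5% and leaves the BH-expected false
discoveries as the dominant (and intended) error source.

### What the generator does and does not emulate

It reproduces the *logical structure* of the inputs — multi-mark peak sets
with condition-specific active promoters, marker-structured NB counts with
a bimodal TF and planted effects, motif-planted promoter sequences — but
not read-level artifacts (no FASTQ/fragment modeling), chromatin covariance
between marks, doublets, batch effects, ambient RNA, or realistic gene-gene
correlation. Passing recovery tests therefore demonstrates that the
pipeline's set algebra, statistics and bookkeeping are correct under
controlled noise; it does not validate peak calling or guarantee
performance on real libraries.

## Problem sizes and runtime

Defaults run the full chain (generate → gate → type → split → test →
intersect) in ~1 s on one CPU: 400 genes, 1,400 cells, ~2,600 peaks across
10 peak sets. The null-calibration simulation uses 1,000 genes × 200 cells.
These sizes were chosen as the smallest at which the statistical behavior
of every stage (type-I error, BH calibration, recovery operating
characteristics) is stable and visible.

## Known limitations

- The DEG stage controls FDR, not family-wise error: with ~20 true
  discoveries at α = 0.05, roughly one false discovery per run is
  *expected*; downstream intersection with the gate absorbs most but not
  all of these (a gate-passing decoy that is also a chance DEG becomes a
  false candidate in a few percent of runs).
- Background H3K27me3 peaks can veto a genuinely active promoter (~1% of
  genes per condition at default background rates); this is realistic noise
  and the main cause of single-target misses.
- The original study's published set sizes (thousands of gated genes, 712
  DEGs, 64 candidates) depend on genome-scale inputs, an external peak
  caller, and unstated spreadsheet DEG settings; this package ships the
  machinery and a documented recipe, not those numbers.
- Marker-score typing assumes marker genes are informative and expressed;
  heavily degraded or marker-poor data would need a different typing stage.
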