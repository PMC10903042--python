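# Methods

## Scope and model

`stressmark` re-implements, as a tested library, a genome-wide H3K4me3
analysis for a factorial drought/heat stress design in a plant genome:
three conditions (unstressed control C, drought DT, drought-then-heat DTHT)
sampled at 0, 72, 96, 120, 144 and 168 h of drought with three replicates
per cell, plus one sonicated-chromatin input library per condition.  Heat is
imposed after 72 h of drought, so "heat-responsive" behaviour is only
observable in the combined treatment from the 96-h sample onward and must be
inferred from two contrasts (DTHT-vs-DT and DTHT-vs-C) rather than a
dedicated heat arm.

The pipeline stages, in execution order:

1. **Ingestion** (`core_io`): aligned reads in BED6 (or BAM via an optional
   adapter) are reduced to strand-aware 5' positions, deduplicated to at
   most `redundancy_threshold` (default 1) reads per (chrom, position,
   strand), and extended to `fragment_size_bp` (default 300 bp) fragments.
   Coordinates are 0-based half-open throughout; GFF3 is converted on read,
   taking the longest mRNA as a gene's representative model and deriving
   introns as inter-exon gaps.
2. **Island calling** (`island_caller`): Poisson-background spatial
   clustering for broad marks.  200-bp windows tile the genome; a window is
   *eligible* when its fragment count `c` satisfies
   `P(X >= c; lambda_w) < p0` with `p0 = 0.2`; runs of eligible windows,
   bridged across gaps up to 200 bp, form candidate islands scored by
   `sum(-ln P(X = c_i; lambda_w))` over their eligible windows.  Each island
   is then tested against its input control: Poisson upper tail of the ChIP
   fragment count with mean equal to the library-size-scaled input count,
   floored at the uniform-background expectation for the island footprint;
   Benjamini–Hochberg FDR across islands, acceptance at FDR <= 0.05.
3. **Differential calling** (`differential`): replicates are pooled per
   group; 200-bp windows stepped every 100 bp are tested with an exact
   conditional binomial test — given the window total `t = a + b`,
   `a ~ Binomial(t, N_A/(N_A + N_B))` under the null of equal per-million
   rates, two-sided p by summing outcome probabilities not exceeding the
   observed one.  Significant (p < 0.01) same-direction windows merge
   (gap 0) into directional peaks carrying the minimum member p and mean
   member RPM values.
4. **Classification** (`stress_classifier`): all differential peaks from all
   comparisons merge single-linkage (>= 1 bp overlap) into a region
   universe.  A region is DT-responsive when not differential in DT-vs-C at
   0 h and differential at >= 1 of 72–168 h; DTHT-responsive by the same
   template on DTHT-vs-C; HT-responsive when not differential in DTHT-vs-DT
   at 0 h nor 72 h and differential in DTHT-vs-C at >= 1 of 96–168 h.
5. **Annotation and profiling** (`annotation_profiling`): single-label
   feature classification, Table-style summaries, signed nearest-TSS
   distances, RPM metaprofiles around TSSs, peak↔gene overlap with 2-kb
   flanks, per-chromosome densities, hypergeometric term enrichment with
   BH adjustment (significant iff adjusted p < 0.05 *and* fold > 1.3), and a
   {0, 1, −1} per-gene export for pathway-viewer consumption.
6. **qPCR** (`qpcr`): 2^−ΔΔCT relative expression against the constitutive
   reference `cons7`, replicates paired by index, reported as mean ± SE of
   per-replicate fold changes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_bp` / `gap_bp` | 200 / 200 | island tiling and bridge distance (bp) |
| `redundancy_threshold` | 1 | max reads per 5' site and strand |
| `effective_genome_fraction` | 0.7 | mappable fraction entering the background rate |
| `island_fdr` | 0.05 | BH FDR acceptance for islands vs input |
| `eligible_window_p` | 0.2 | Poisson tail for window eligibility (tool default) |
| `diff_window_bp` / `diff_step_bp` / `diff_gap_bp` | 200 / 100 / 0 | differential window grid |
| `fragment_size_bp` | 300 | sonication fragment extension |
| `diff_p_cutoff` | 0.01 | raw per-window significance cutoff |
| `min_diff_peak_windows` | 2 | min member windows per reported differential peak |
| `min_diff_fold` | 1.5 | min between-group RPM ratio per reported peak |
| `flank_bp` | 2000 | upstream/downstream flank for annotation and overlap |

## Numerical and design choices

* **Background rate.** Fragments are counted in every window they overlap by
  >= 1 bp, which keeps island counts additive.  Under that counting rule a
  fragment of size F can touch a W-bp window from W + F − 1 start positions,
  so the per-window background rate is `lambda_w = N(W + F − 1)/(L·f)` with
  L the genome length and f the effective fraction.  A point-count formula
  (`NW/(L·f)`) would understate the null mean ~2.5-fold here and make nearly
  every window eligible, collapsing islands into chromosome-scale runs.
* **Restriction of differential testing.** Windows are tested only where the
  pooled A+B signal forms a Poisson-eligible cluster.  Regions whose
  coverage is compatible with pure background cannot support a meaningful
  rate comparison, and testing them turns the raw p < 0.01 cutoff into a
  genome-wide false-call generator (~0.8% of all windows).  This mirrors how
  differential ChIP tools confine testing to covered regions.
* **Peak-level floors.** A reported differential peak must contain >= 2
  significant member windows and a between-group RPM ratio >= 1.5.  Both
  floors target the residual null failure mode: inside strong constitutive
  domains the counts are large, so ~1.1-fold sampling wobbles reach nominal
  significance, and because 200-bp windows at 100-bp step share fragments,
  one wobble spans several correlated windows.  A fold floor alongside a p
  cutoff is standard in differential enrichment callers; 1.5 sits far below
  biologically meaningful effects while removing count noise.  The
  window-level test and the merge operation themselves are unfiltered and
  are exercised directly by the unit suite.
* **No correction at the differential stage.** The raw 0.01 cutoff is kept
  deliberately; FDR control enters only at the island-vs-input stage.
* **Region identity.** "The same region" across contrasts and time points is
  defined by single-linkage overlap merging — the least-assumptive
  construction that gives every differential peak a persistent coordinate
  identity.  Baseline exclusions ("not differential at 0 h") are evaluated
  against the merged region: it must overlap no differential peak of the
  relevant contrast at the excluded time point.
* **Rule overlap is real.** The three class rules are set-logical and not
  mutually exclusive.  In particular, any sustained drought effect (present
  in both DT and DTHT) also satisfies the HT rule, because the DTHT-vs-DT
  contrast is only constrained at 0 and 72 h; and any HT-responsive region
  is also DTHT-responsive unless it is differential in DTHT-vs-C at 0 h.
  The classifier imposes no exclusivity, and the synthetic ground truth
  records the *expected rule classes* of each implanted island — derived by
  applying the rules to its analytic activity pattern — so that recovery is
  scored against what the rules imply rather than the generative label only.
* **Feature precedence.** One label per peak, decided at the peak midpoint
  with precedence 5'UTR > CDS > 3'UTR > intron > upstream > downstream >
  repeat > intergenic (flanks strand-aware, 2 kb).  The choice is
  centralised in `classify_feature` so a whole-peak-overlap variant is a
  local change.  Nearest-TSS ties break on the lexicographically smaller
  gene id for determinism.
* **qPCR SE** is computed on per-replicate fold changes (the displayed
  scale), not on ΔΔCT.

## The synthetic experiment

`synthetic_data.TruthSpec` defaults define the study conditions: a
2 × 500 kb genome, 100 non-overlapping two-exon genes (2 kb; 5'UTR 10%,
CDS 30%, intron 20%, CDS 30%, 3'UTR 10%), ~15% of the genome in intergenic
repeats, 30 background fragments/kb per library (~30 fragments per island
per library), 300-bp fragments, and 12 implanted 1-kb islands per class
(DT, DTHT, HT, constitutive) at effect multiplier 4, placed at
[TSS, TSS + 1 kb) of distinct genes in transcription orientation — where
this activating promoter-proximal mark concentrates.  Onsets are drawn from
{72, 96, 120} h for DT, {72, 96} h for combined-stress islands, and
{96, 120} h for heat islands (heat cannot act before the 96-h sample).
Input libraries are background-only.  The full 57-library experiment
generates and classifies end to end in well under a minute, which is the
problem size used by the test suite and the acceptance script.

What the generator does *not* emulate: sequence-level artefacts
(mappability, GC bias), fragment-length variation, replicate-specific
efficiency differences, antibody off-target binding, or copy-number
structure.  Passing the recovery suite therefore demonstrates correctness
of the statistics and rule logic under the design's own assumptions, not
robustness to real-data systematics.

## Degenerate inputs and edge handling

Empty ChIP or input libraries, empty genomes, unknown chromosomes,
out-of-bounds reads (genome/annotation mismatch), step > width grids, gap
sizes not multiples of the window, non-positive CTs and missing reference
genes are hard errors.  Chromosome ends produce a final short window that
participates normally.  Fragments are clipped, never dropped, at chromosome
edges.  Zero-difference windows get p = 1 exactly.  Overlapping
opposite-direction peaks (possible with step < width) cede the contested
overlap to the smaller-p peak, splitting at the midpoint on ties.

## Known limitations

* The conditional binomial test models pooled counts and ignores
  between-replicate dispersion; per-replicate concordance is available in
  the outputs but does not gate calls.
* Island p-values inherit a selection effect (candidates are chosen for
  high ChIP counts before being tested against input); the
  background-floored input expectation and the BH layer keep the realised
  null rate conservative (measured well under 5% of fully-null simulations
  with any call), but the per-island p-values should not be read as
  calibrated beyond that use.
* The published per-condition peak totals from the original deposited data
  are data-dependent outcomes and are out of scope; arithmetic consistency
  of the published feature-distribution table is checked instead.
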