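# Methods

## Scope and model

`sdscan` implements the three statistical designs used to characterize a
small XY sex-determining region (SDR) in a species without cytogenetically
differentiated sex chromosomes:

1. a pooled-sequencing (Pool-Seq) scan for sex-specific SNVs and coverage
   anomalies,
2. a RAD-seq presence/absence sex-association screen, and
3. 2×2 chi-square linkage statistics for individual genotyping assays.

All three sit downstream of read mapping and allele counting: the package
consumes count tables (sync-style per-site pool counts, marker × individual
depth matrices, Ho/He/Uncalled assay counts), never reads or alignments.

### Pool-Seq site model

With male heterogamety, every male carries one X and one Y haplotype. At a
site where the X and Y alleles differ, the male pool's expected
alternate-allele frequency is 0.5 and the female pool's is 0 (plus
sequencing error). A site is called **male-specific** when the male pool is
heterozygous — the frequency of its second most frequent base lies within
`0.5 ± het_delta` of the A/C/G/T total — and the female pool is homozygous
(major-base frequency ≥ `hom_min_major`); **female-specific** is the exact
mirror. N and deletion counts are excluded from denominators. Pools below
`min_depth` exclude the site.

Defaults: `het_delta = 0.1`, `hom_min_major = 0.98`, `min_depth = 10`.
The heterozygosity band accepts binomial sampling noise around 0.5 at ~40×
pool depth; `hom_min_major = 0.98` means a single stray read at 40×
(frequency 0.025) breaks homozygosity — a strict choice that keeps the
false-positive rate of the classifier near zero (measured ≈ 0.36 false
sex-specific calls per 6-Mb null genome) at the cost of per-site detection
power ≈ 0.74 at 40× with 10⁻³ sequencing error. Both thresholds are exposed;
noisier data may warrant `hom_min_major ≈ 0.97`.

### Window tracks and region calling

Windows of `window_size` (default 5,000 bp) are placed every
`output_resolution` (default 1,000 bp); a site contributes to every window
whose half-open span contains it, so an interior SNV is counted
`window_size/output_resolution` times across the sliding track, and exactly
once in the non-overlapping `manhattan_bin` (default 50 kb) export. Window
depth means average all recorded sites (variant records plus the generator's
dense per-kilobase depth records when present).

SDR calls are maximal runs of windows holding at least `min_count`
sex-specific SNVs, tolerating up to `max_gap` consecutive sub-threshold
windows; runs with fewer than `min_windows` qualifying windows are dropped,
and a region spans first-qualifying-window start to last-qualifying-window
start + `window_size`. Defaults `min_count = 2`, `min_windows = 10`,
`max_gap = 10` were fixed by a design study on the reference scenario
(divergent-site rate 10⁻³/bp, 40× pools, error 10⁻³): with per-site
detection ≈ 0.74 the expected count per 5-kb window is ≈ 3.6, so demanding
≥ 5 SNVs per window produces no call at all and ≥ 3–4 fragments the region;
at `min_count = 2` the background is clean enough (see above) that the run
criterion, not the per-window threshold, carries the specificity: 10
enriched windows are never produced by isolated false positives, and 50
null genomes yielded zero region calls while 20 SDR genomes gave 20/20
top-call recovery with called lengths 101–108 kb for a true 100-kb region.
Overlapping candidates are ranked by total SNV support, ties to the leftmost
start.

### Hemizygosity (Y-limited insertion) caller

Sequence present only on the Y is covered by a single haplotype in males
and absent in females: at a 40× pool design depth, males show ≈ 20× and
females ≈ 0×. `coverage_regions` flags windows with female depth ≤
`f_max_frac` (default 0.1) of the genome-median female depth and male depth
within `m_band` (default [0.35, 0.65]) of the genome-median male depth, then
merges runs exactly like the SDR caller. Genome medians of zero are
rejected rather than guessed around.

### RAD screen

Presence = depth ≥ d (default d = 1). The tile matrix T[m][f] counts
markers by (males present, females present); each occupied cell except
(0, 0) is tested with an *uncorrected* Pearson chi-square (df = 1) on
[[m, n_males−m], [f, n_females−f]]; tables with an empty column margin
(present or absent in everyone) carry no signal and score 0. Significance is
Bonferroni over occupied cells — markers in one cell share a p-value, so the
cell is the natural testing unit; correcting over markers instead would be
more conservative for large panels and is a one-line change. The continuity
correction is deliberately *not* applied here, while the assay statistics
below apply it; the two conventions are implemented separately on purpose.

### Genotyping-assay statistics

`yates_chi2` computes Σ(|O−E|−½)²/E with the corrected deviation clamped at
0, p from the df = 1 upper tail. Tables with a zero row or column margin
raise an explicit undefined-test error; a degenerate screen (e.g. one fish
per sex) is reported as uninformative rather than silently non-significant.
For Ho/He/U tables the tested 2×2 is [[male_he, male_ho], [female_he,
female_ho]] — uncalled genotypes are excluded; including them as negatives
conflates assay failure with genotype and does not reproduce the behaviour
of standard assay panels. Conventions for the summary percentages: `%N` =
assayed individuals / recruited cohort (cohort size is an input); `%As` =
sex-concordant calls (He males + Ho females) / assayed individuals; the
called-only variant of %As is also computed (`pct_assigned_called`) but the
assayed-total convention is the one reported. p-values below 2.22·10⁻¹⁶ are
formatted "< 2.2e-16" while the numeric field keeps the computed value.

## Synthetic data generator

`simdata` emulates the study conditions the analyses assume:

* genome: arbitrary chromosomes; defaults used throughout tests and the
  acceptance script are 3 × 2 Mb with a 100-kb SDR and a 53-kb Y-limited
  insertion — sizes chosen so a full scan runs in seconds while windows,
  runs and medians behave as on a real genome;
* cohorts: 35 males / 34 females (the RAD fixture convention), pool depth
  40× per pool;
* background polymorphism: per-site population frequency ~ Beta(0.7, 0.7)
  drawn once and shared by the sexes; each pool's haplotype frequency is a
  binomial draw of its 2n haplotypes, so pools differ realistically and the
  classifier must reject these sites;
* SDR: divergent sites at 10⁻³/bp, male pool exactly 0.5 / female 0 before
  error; y-insertion: female Poisson mean 0, male mean halved;
* errors: per-read substitution to a uniform other base at 10⁻³; RAD
  dropout per cell (default 0 so the default scenario reproduces the
  canonical single-marker screen: one Y-limited marker present in all
  males, absent from all females); genotyping error flips He↔Ho at 2% and
  missingness moves calls to U at 4% by default;
* background SNP rate 0.005/bp is a placeholder — the true pool
  heterozygosity of wild perch is not established — and is exposed in
  `SimParams`.

Everything is driven by one `numpy` Generator seeded from `SimParams.seed`;
identical parameters give byte-identical outputs. What the generator does
**not** model: read-level artifacts (mapping bias, MAPQ filtering, indel
realignment), linkage disequilibrium outside the SDR, GC-coverage bias, and
RAD allele dropout correlated with restriction-site polymorphism. Passing
tests therefore demonstrate correctness of the statistics and the calling
logic under the stated sampling model, not robustness to alignment
artifacts in real data.

## Numerical and design choices

* Coordinates are 0-based half-open internally; sync files and report TSVs
  are 1-based (stated in their headers); BED exports are 0-based half-open.
* Chi-square tails come from `scipy.stats.chi2.sf`; tests verify both the
  RAD and the Yates statistics against the independent closed-form identity
  p = erfc(√(χ²/2)) on randomized tables to 10⁻¹⁰ relative error.
* Site classification is exhaustively checked against a brute-force
  re-evaluation of the frequency rules over all 455 × 455 count
  compositions at depth 12; window placement, run merging, coverage
  flagging and gene overlap each have independent brute-force oracles in
  the test suite.
* Degenerate inputs fail loudly: zero-margin 2×2 tables, unsorted site
  tables (reported with the first offending position), malformed sync/GFF3
  lines (reported with line numbers), zero-median coverage, single-sex RAD
  cohorts.
* The label symmetry of the scan (swapping pool columns swaps
  male/female-specific calls exactly) is a tested invariant; the generator
  itself is not label-symmetric under a fixed seed because the draw order
  differs.

## Known limitations

* The sliding-window track reports every window start even on long
  chromosomes; memory is linear in genome length / `output_resolution`
  (fine to ~1 Gb at 1-kb resolution, not tuned beyond that).
* The RAD screen's chi-square is asymptotic; for very small cohorts an
  exact test would be preferable (out of scope here, as the screen's role
  is ranking cells under Bonferroni).
* Region length estimation inherits a ±1 window-size quantization; called
  lengths for a 100-kb region vary by a few kb across seeds.
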