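# Methods

`pesca` implements the computational core of a paralleled enhancer
single-cell assay: selecting a panel of candidate enhancers (gene
regulatory elements, GREs) from comparative ATAC-seq, designing the viral
reporter barcodes that tag each GRE, deconvolving single-nucleus barcode
reads into UMI count matrices, and testing each GRE for cell-type-specific
expression. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## GRE panel selection

Inputs are peak intervals (0-based half-open, BED convention), a peaks x
cell-type matrix of mean ATAC signal, and per-peak conservation scores
(mean phyloP-style values; computing them from alignments is out of scope).

1. **Merging.** Overlapping peaks are unioned into a non-redundant
   reference list. Book-ended intervals (end of one equals start of the
   next) are *not* merged: half-open intervals that touch share no base.
   This differs from `bedtools merge` defaults, which is why the merge is
   implemented directly and checked against a boolean genome-mask oracle.
2. **Conservation cutoff.** For each peak a length-matched control
   interval is placed 100,000 bp downstream (mirrored upstream when the
   chromosome end intervenes; peaks admitting neither placement are
   dropped and reported). The cutoff is the 95th percentile of the control
   score distribution, using the nearest-rank definition
   (ceil(p/100·n)-th order statistic) — exact on small fixtures and
   directly testable as an order statistic. Whether controls should also
   be required not to overlap other peaks is unresolved; no such exclusion
   is applied.
3. **Specificity score.** Each cell-type signal column is scaled to a
   common total (default 1e7); the per-peak score is
   (target + 0.5) / (mean of non-target columns + 0.5). The non-target
   aggregate is the arithmetic mean over all non-target columns, which
   generalizes the two-column case to any number of cell types. The score
   is scale-free: multiplying all raw signal by a constant is absorbed by
   the normalization.
4. **Ranking.** Peaks are ranked by score; ties break by higher target
   signal, then input order, making the panel deterministic. Default panel
   size is 287.

## Barcode design

Reporter barcodes are ACGT 10-mers, all pairwise separated by at least 3
edits so a single sequencing error cannot move a read from one barcode's
neighbourhood into another's. Two metrics are available: plain Levenshtein
(via edlib) and Sequence-Levenshtein, the barcode-design variant that also
penalizes boundary frame shifts (minimum over the last row and column of
the edit-distance DP table). Which of the two governed the published
1164-barcode pool is ambiguous (two chained design calls with different
settings), so both are exposed and neither is asserted as canonical.

Sets are built by a *seeded greedy closure*: candidates are visited in a
seeded shuffle of lexicographic order (or plain lexicographic order, which
makes the closure reproducible against a brute-force oracle) and kept iff
they are at least `min_dist` from every kept barcode. This was chosen over
evolutionary search because determinism and verifiability matter
downstream while exact set membership does not; pool sizes comparable to
the published 1164 are not guaranteed and not asserted. Two accelerations
keep design of 861 10-mers under a second: a vectorized Hamming prefilter
(Levenshtein ≤ Hamming, so Hamming < min_dist is a certain violation) and
a SymSpell-style deletion-neighbourhood index (two words within
Levenshtein d share a common subsequence reachable by ≤ d deletions from
each). Every designed set is verified by an exhaustive O(n²) pairwise
check. Each GRE then receives `per_gre` (default 3) barcodes by seeded
sampling without replacement; 287 GREs x 3 = 861 pairs.

## Read deconvolution

Reads are (cell barcode, UMI, observed 10-mer) records; fixed vector
flanks are trimmed by exact prefix/suffix match upstream. Observed
sequences are compared to the designed set by Hamming distance over the
fixed-length window — substitution-only matching, because the mapper being
emulated allowed at most one mismatch against a fixed contig; indel
tolerance is deliberately out of scope. The assignment policy reconciles
two constraints from different layers of the original pipeline (mapping at
≤ 1 mismatch; uniqueness within 2 mismatches) into one rule:

* **assigned** — exactly one barcode within `max_mismatch` (1) *and* no
  second barcode within `uniqueness_radius` (2);
* **ambiguous** — two or more barcodes within the radius;
* **unassigned** — otherwise.

Because a validated set has pairwise distance ≥ 3, two barcodes within one
mismatch of the same read are impossible; this is asserted at match time
rather than assumed. Duplicate (cell, UMI, barcode) triples collapse to one
molecule; UMI dedup is exact-match only (no UMI error correction), since
the emulated pipeline condensed exact barcode–UMI combinations. The QC
report tracks the fraction of viral reads not uniquely assignable — the
library-integrity statistic a screen reports. GRE-level counts are the sum
of the GRE's barcode columns; count conservation through aggregation is
asserted on every run. A cell whitelist is optional; absent one, all
observed cell barcodes are kept (cell calling is upstream).

## Enrichment statistics

**Normalization.** `ln(1 + count / cell_total * 10000)`. Cell totals are
row sums of the supplied matrix — here viral totals only, because the
non-viral transcriptome is not simulated; external totals can be passed
when available. Zero-total cells are flagged and excluded.

**Fold enrichment.** `(mean_target + 0.01) / (mean_rest + 0.01)` per
feature, computed on normalized expression by default (`use_normalized`)
with raw-count mode available; which scale the published fold values used
is not stated, so both are exposed. GRE-level expression is the per-cell
sum of the GRE's three barcode slots on the same scale the fold is taken
on. The 0.01 pseudocount is treated as a fixed configuration constant.

At screen-like depth (≈ 0.05 UMIs per cell per GRE in non-target cells)
this estimator is mildly conservative: the pseudocount pulls extreme
ratios toward 1, and the log1p transform saturates multi-count cells. In
simulation with a true 8.3-fold GRE the recovered estimate averages ≈ 7.4
(about 10% low) — within the 15% band the fold-recovery check uses, and a
property worth remembering when reading absolute fold values at low depth.

**Triplet consistency.** Per-barcode log2 folds are arranged into
`barcodes_per_gre` slot vectors (map order) and all pairwise Pearson r
reported with two-sided p; zero-variance slots yield undefined r, reported
as NaN. The permutation null shuffles the value-to-(GRE, slot) assignment
uniformly per shuffle and records the mean pairwise r; under
exchangeability its mean is 0 and its spread is on the 1/sqrt(n_GREs - 1)
scale (slightly below, since the three pairwise r's are nearly
uncorrelated).

**NB likelihood-ratio test.** Counts per GRE are modeled NB2
(var = mu + alpha·mu²) with a log link and log size-factor offset; the
full model adds a target-cell indicator to the intercept-only reduced
model; twice the log-likelihood gap is referred to chi-square(1).
Dispersion is estimated per feature by maximum likelihood jointly with the
means (L-BFGS-B on the exact likelihood with analytic gradients,
method-of-moments initialization, Nelder-Mead fallback; log-alpha bounded
in [-12, 6]). All-zero features get p = 1; non-convergent features are
flagged and excluded from the Benjamini–Hochberg denominator. Size factors
are total-count by default (median-of-ratios available). When testing a
feature *subset*, size factors must be supplied from the full library
matrix — totals over a handful of uniformly enriched features would absorb
the group effect into the offset; the pipeline does this automatically.
A feature is called enriched when BH q < 0.01 and fold > 1. Under permuted
labels the test holds its nominal 0.05 level within ±0.02 in simulation.

**Subsampling power.** Each count c is replaced by a Binomial(c, p) draw
for p in (0.5, 0.25, 0.125, 0.0625), ten replicates each (independent
derived seeds), and the NB-LRT rerun; the report gives per-feature
detection rates by thinning probability. Detection degrades monotonically
in expectation as depth falls.

## Synthetic screen generator

The generator produces every input the pipeline consumes, with known
ground truth, under the screen's study conditions: 287 GREs x 3 barcodes;
ten cortical cell types with excitatory neurons dominant and a ~5% SST
target population; 86% of cells infected; 15.6 viral UMIs per cell on
average. Per cell: the type is drawn from the composition; with
probability `infection_fraction` the cell receives a negative-binomial
total UMI count; each UMI is allocated to one GRE-barcode slot by a
multinomial whose GRE weights are multiplied by `true_fold` in target
cells; each UMI is emitted as `duplication_factor` reads whose barcode
carries i.i.d. per-base substitution errors. UMI words are distinct within
a cell by construction, so error-free simulation round-trips exactly
through dedup. Identical seeds give byte-identical output.

Parameter notes:

* `mean_viral_umis_per_cell` (15.6) is the mean over *all* cells; infected
  cells draw totals with mean 15.6/0.86, so the overall mean and the 86%
  infected fraction hold simultaneously (both verified empirically at
  n = 10,000).
* `nb_dispersion` (0.25) is a free parameter — the dispersion of viral UMI
  totals is not constrained by any published value; 0.25 is modest
  overdispersion typical of droplet snRNA-seq totals.
* `barcode_error_rate` (0.005/base) yields ≈ 5% of reads with at least one
  substitution, comparable to Illumina barcode-region error burden.
* The multinomial allocation renormalizes across GREs, so the realized
  target/non-target count ratio of a hit is `true_fold · n_GREs / Σ fold`
  (a 2–3% shrink for a single planted hit); tests against ground truth use
  this design ratio.

What the generator does *not* emulate: the non-viral transcriptome
(cell-type labels are supplied directly — clustering is out of scope, and
normalization therefore runs on viral totals), droplet artifacts (ambient
RNA, doublets, barcode swapping), per-animal batch structure, and GRE
abundance skew in the viral library (per-GRE weights are uniform by
default). Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under a faithful count model,
not robustness to every artifact of real droplet data.

The peak fixture for the selection stage plants `n_specific` peaks with
elevated target-column signal (gamma baseline, 6x elevation) and gives
designated conserved peaks conservation scores strictly above the 95th
percentile of a matched control distribution (and all others strictly
below), so ground-truth flags are unambiguous by construction.

## Problem sizes and determinism

Simulation-backed checks use 10,000-cell screens for depth-sensitive
quantities (fold recovery, significance of planted hits, generator
anchors), 3,000–4,000 cells for calibration checks (type-I error, shuffle
null), and a few hundred cells for round-trip and plumbing tests. All
randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawning; per-shuffle and per-replicate streams are derived from one
master seed, and reruns with the same seed are byte-identical (asserted
for the full pipeline).

## Known limitations

* Hamming-only read matching cannot rescue reads with indels in the
  barcode window.
* Per-feature ML dispersion is noisy for very sparse features; the
  chi-square(1) reference is asymptotic, and the observed mild
  conservatism at extreme sparsity is accepted rather than corrected.
* The fold estimator's depth-dependent downward bias (above) means
  absolute fold values at low coverage should be read with the
  subsampling power analysis alongside.
* Distal control intervals may overlap other peaks; no exclusion is
  applied.
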