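# pesca

Toolkit for paralleled enhancer screens with a single-nucleus readout.

Enhancer-driven viral vectors are the most promising route to genetic
access to specific cell types, but finding an enhancer (gene regulatory
element, GRE) that restricts expression to one rare population means
testing hundreds of candidates across every cell type of a tissue at once.
A paralleled enhancer single-cell assay does this by cloning a pooled
library of GRE-driven reporters, tagging each GRE's transcript with short
DNA barcodes in the 3'UTR, delivering the pool *en masse*, and reading the
barcodes out by single-nucleus RNA-seq — so each nucleus reports which
GREs are active in its cell type.

`pesca` implements the computational side of such a screen, end to end:

* **GRE selection** — merge ATAC-seq peak lists (0-based half-open),
  threshold conservation at the 95th percentile of distal length-matched
  controls, score cell-type specificity as
  (target signal + 0.5)/(mean non-target signal + 0.5) after scaling each
  population to 1e7 total signal, and rank the top-k panel (default 287);
* **barcode design** — DNA 10-mers all pairwise ≥ 3 edits apart
  (Levenshtein or Sequence-Levenshtein), built by a seeded greedy closure,
  exhaustively validated, and assigned 3-per-GRE (287 × 3 = 861 pairs);
* **barcode deconvolution** — Hamming matching of reads to the designed
  set (assigned iff unique within 1 mismatch and no competitor within 2),
  exact (cell, UMI, barcode) dedup, cell × barcode and cell × GRE count
  matrices with QC;
* **enrichment statistics** — log-normalized expression
  ln(1 + c/total·10⁴), pseudocounted fold
  (mean<sub>target</sub> + 0.01)/(mean<sub>rest</sub> + 0.01),
  barcode-triplet Pearson consistency with a shuffle null, a per-feature
  negative-binomial likelihood-ratio test (NB2 GLM, log link, size-factor
  offset, ML dispersion, χ²(1)) with Benjamini–Hochberg FDR, and a
  binomial-thinning power analysis;
* **a synthetic-screen generator** — ten cell types with a rare (~5%)
  target population, 86% infection, NB-distributed viral UMI totals
  averaging 15.6 per cell, multinomial UMI allocation with known true
  fold-enrichments, and sequencing errors on barcodes — so the whole
  pipeline is testable with known ground truth and no sequencing data.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Simulate a screen at realistic depth (10,000 nuclei, 287 GREs, three
planted hits with true folds 8.3, 9.1, 7.2 in the Sst population),
deconvolve the reads, and test every GRE:

```python
import numpy as np
from pesca import (ScreenTruth, simulate_screen, count_umis,
                   aggregate_gre, nb_lrt_test)
from pesca.stats import screen_folds, shuffle_null

truth = ScreenTruth(true_fold={"GRE012": 8.3, "GRE019": 9.1, "GRE022": 7.2})
scr = simulate_screen(truth, 10_000, seed=1)
mat, qc = count_umis(scr.reads, scr.barcode_set,
                     cell_whitelist=scr.labels["cell_barcode"].tolist())
gre = aggregate_gre(mat, scr.gre_map)
table = nb_lrt_test(gre, scr.labels, "Sst")
bc_folds, gre_folds = screen_folds(mat, scr.labels, scr.gre_map, "Sst")
table["fold"] = gre_folds.loc[table.index]
null = shuffle_null(np.log2(bc_folds), scr.gre_map, n_shuffles=1000, seed=1)
```

Output:

```
reads: 156615  deduplicated UMIs: 154675  unassignable read fraction: 0.0124
         mean_target  mean_rest    fold      q  enriched
feature
GRE022        0.4637     0.0544  7.6055  0.000      True
GRE019        0.4536     0.0559  7.3246  0.000      True
GRE012        0.3770     0.0543  6.1856  0.000      True
GRE137        0.0262     0.0552  0.4617  0.138     False
triplet consistency: observed mean r = 0.276; shuffled null = -0.0005 +/- 0.035
```

The three planted hits dominate the ranking: their raw per-cell counts are
~7–8× higher in target nuclei (`mean_target` vs `mean_rest`), the
pseudocounted fold estimates sit near (slightly below — see the methods
note on estimator bias at this depth) their true values, and all three
reach q ≈ 0 in the NB test while no null GRE is called enriched.
Enrichment values computed independently from each GRE's three barcodes
correlate (mean pairwise r = 0.28); shuffling the values across GREs
destroys the correlation (0.000 ± 0.035), confirming the signal is carried
by the GRE, not the barcode. About 1% of reads are unassignable — reads
whose sequencing errors leave them without a unique barcode within the
mismatch policy.

The same flow is available from the shell:

```sh
pesca simulate --n-cells 10000 --seed 1 --out sim/
pesca count  --reads sim/reads.tsv --barcodes sim/barcodes.tsv \
             --map sim/gremap.tsv --out counts/
pesca enrich --counts counts/ --labels sim/labels.tsv \
             --map sim/gremap.tsv --target Sst --out results/
pesca run    --config cfg.yaml --seed 1 --out run/   # all stages + manifest
```

plus `pesca select` (GRE panel from peak/signal/conservation tables),
`pesca barcodes` (set design), and `pesca power` (subsampling analysis).
Every run writes a manifest with seeds, versions, and input hashes;
identical seeds reproduce outputs byte-for-byte.

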