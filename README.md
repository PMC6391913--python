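# qsep

Quantitative assessment of sub-cellular resolution in spatial proteomics
(fractionation profile) experiments.

Given a proteins × fractions quantitation matrix and a curated marker
annotation (organelle labels for a trusted subset of proteins), the
package computes:

- the **raw cluster distance matrix**: average Euclidean distance of the
  full n-dimensional protein profiles within (diagonal) and between
  (off-diagonal) marker clusters;
- the **normalised separation matrix**: each row divided by that
  reference cluster's within-cluster average, giving an asymmetric
  matrix with unit diagonal — entry (i, j) is "how far is cluster j from
  cluster i, in units of cluster i's own spread";
- the **experiment-wide median** of the k(k−1) off-diagonal normalised
  entries, a single comparable resolution score per experiment.

Missing quantitation values are preserved for distance computations
using the scaled pairwise-complete convention
`d = sqrt((p/m) · Σ_complete (x_f − y_f)²)` (identical to base R's
`dist`), and are only zero-imputed in an explicit view used by PCA and
plotting. Clusters backed by fewer than 7 markers are dissolved by
default.

Also included: marker transfer between datasets, a class-removal
robustness scan with least-squares slope, a Welch t-test comparison of
log separation scores, diagnostic plots (PCA scatter/hexbin/annotated,
profile line plots, marker dendrograms, separation heatmaps and
boxplots), and a seeded synthetic data generator with known ground
truth.

## CLI

All subcommands read delimited text (TSV by default): one protein-id
column (first column by default), numeric fraction columns, and an
optional marker column (`--markers-col`, default `markers`).

```sh
# simulate a marker-structured dataset
qsep simulate --k 5 --p 10 --n 30 --delta 1.0 --sigma 0.1 --seed 42 --out sim.tsv

# raw + normalised matrices and summary JSON
qsep compute --input sim.tsv --markers-col markers --min-markers 7 --out results/sim

# diagnostics
qsep plot --input sim.tsv --style hexbin --out fig_hexbin
qsep plot --input sim.tsv --style annotated --out fig_annotated
qsep plot --input sim.tsv --style qsep --out fig_qsep --min-markers 5

# transfer markers from one dataset onto another, then score
qsep transfer --source a.tsv --target b.tsv --markers-col markers

# class-removal robustness scan
qsep robustness --input sim.tsv --max-removed 3 --out results/rob

# compare two experiments (Welch t-test on log scores)
qsep compare a.tsv b.tsv
```

Exit code 0 on success, 2 on input/validation errors. Everything the
CLI does is available through the library API (`import qsep`).

## Reproducing published numbers

The benchmark computations (`tests/test_acceptance.py` criteria 1–4 and
`scripts/acceptance.py`) run on flat exports of datasets distributed in
the Bioconductor `pRolocdata` package. Those data cannot be bundled
here. To produce the exports, run in R (with `pRolocdata` and `MSnbase`
installed):

```r
library(pRolocdata)
library(MSnbase)
export <- function(name) {
  data(list = name)
  obj <- get(name)
  tab <- data.frame(exprs(obj), check.names = FALSE)
  tab$markers <- as.character(fData(obj)$markers)
  write.table(cbind(id = rownames(tab), tab),
              file.path("data/external", paste0(name, ".tsv")),
              sep = "\t", quote = FALSE, row.names = FALSE, na = "NA")
}
dir.create("data/external", recursive = TRUE, showWarnings = FALSE)
for (n in c("hyperLOPIT2015", "itzhak2016stcSILAC", "E14TG2aS1", "foster2006"))
  export(n)
```

Place the four TSVs under `data/external/` in the repository root (or
set `QSEP_DATA_DIR`), then:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script recomputes, per dataset: the experiment-wide median
normalised separation score, the cross-dataset marker-transfer scores,
the class-removal slopes, the missing-value percentage, and the PC1+PC2
variance. Targets whose export is absent are omitted with a note on
stderr; the script still exits 0.
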