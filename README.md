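# probetest

Probe-level differential expression testing for two-condition microarray
data — without background correction or summarization.

The method: quantile-normalize the probe intensity matrix across arrays,
compute a pooled two-sample t statistic **per probe** directly on the
normalized intensities (the t statistic is scale- and location-invariant,
so under the linear intensity model `Y = B + phi * theta` this is
equivalent to testing the concentration itself), aggregate each gene's
probe t values by their **median**, and rank genes by descending absolute
median t. Analytic p-values come from the null distribution of the median
of n i.i.d. Student-t variates (closed form for odd n; for even n the
corrected density of the mean of the two central order statistics,
evaluated by adaptive quadrature — the naive even-n expression with
constant `n!/((n/2)!)^2` is not a density and is kept only as a documented
`printed_even_median_t_pdf`).

The package also ships:

* `probetest.spikein` — a synthetic Latin-square spike-in generator
  (default: 42 spiked genes in 14 concentration groups × 3 replicate
  arrays, doubling series 0, 0.125 … 512 pM, 11 probes per gene) with the
  cyclic rearrangement into 14 two-condition experiments (39 truth genes
  at fold change 2 each, one wrapped gene group excluded), plus a generic
  two-condition simulator and an imperfect background-correct-then-
  summarize baseline.
* `probetest.evaluation` — average ROC over rearranged experiments and
  mean top-N gene-list overlap under random subsampling (robustness).

## CLI

All data files are plain TSV (see `probetest.data` docstring for the
dialects). Logs go to stderr; exit codes are 0 (ok), 1 (validation /
usage), 2 (I/O).

```sh
# quantile normalization only
probetest normalize --in matrix.tsv --map map.tsv --out normalized.tsv

# the probe-level median-t test (normalizes internally unless --no-normalize)
probetest test --in matrix.tsv --map map.tsv --labels labels.tsv \
    --out results.tsv [--no-normalize] [--sided one|two]

# simulate a Latin-square spike-in dataset (YAML config optional)
probetest simulate latin-square --config design.yaml --seed 1 \
    --out-prefix sim/ [--n-null-genes N] [--probes-per-gene K] [--noise-cv C]

# average ROC over the 14 rearranged experiments
probetest evaluate roc --sim-prefix sim/ --method median-t|gene-t --out roc.tsv

# top-N overlap robustness
probetest evaluate robustness --in matrix.tsv --map map.tsv \
    --labels labels.tsv --subsample-size 24 --n-subsamples 100 \
    --n-top 100 --seed 1 --out overlap.tsv
```

Example `design.yaml`:

```yaml
design:
  n_groups: 14
  genes_per_group: 3
  replicates: 3
  n_null_genes: 2000
  probes_per_gene: 11
model:
  noise_cv: 0.2
  background_median: 100.0
  affinity_median: 1.0
```

## Library sketch

```python
import probetest as pt

matrix = pt.read_probe_matrix("matrix.tsv", "map.tsv")
design = pt.read_labels("labels.tsv")
results = pt.run_probe_level_test(matrix, design)   # ranked GeneTestResult list
pt.write_results(results, "results.tsv")

dist = pt.MedianTDistribution(n=11, df=design.df)   # analytic median-t null
p = dist.p_value(results[0].median_t)
```

## Notes & assumptions

* Probes of one gene are treated as independent draws for the median-t
  null; no dependence correction is applied.
* Genes are ranked by |median t| (direction-agnostic); default p-values
  are two-sided — for a fixed probe count the two orderings agree.
* Zero pooled variance gives t = 0 for equal means and a signed-infinity
  sentinel otherwise; infinite medians rank first with p = 0.
* Ties under quantile normalization receive the mean reference value over
  the tied rank range, so equal inputs map to equal outputs; exact
  multiset sharing across columns holds for tie-free columns.
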