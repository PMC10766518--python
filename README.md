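# activesvm

Active-learning construction of **minimal marker-gene panels** for
classifying cell states in single-cell expression data.

Targeted transcriptomic assays (probe panels, seqFISH, clinical qPCR) can
only measure tens of genes, so a central design problem is: given a labelled
scRNA-seq atlas, which small gene set preserves the ability to tell the cell
classes apart?  This package builds such panels greedily with a linear
support vector machine (SVM), analyzing the full transcriptome only for the
handful of cells the current panel classifies poorly — which keeps both
memory and the number of cells ever touched small.

## The procedure

Cells `i = 1..N` carry expression vectors `x_i` over `M` genes and integer
class labels `y_i` (from clustering, metadata, or perturbation identity).
With the current panel `J`, one iteration does:

1. **Classify.** Fit a soft-margin linear SVM (hinge loss, regularization
   `C`; one-vs-rest for `Z > 2` classes) on all training cells restricted to
   `J`, and record train/test accuracy.
2. **Find hard cells.** By the KKT conditions of the SVM dual, a training
   cell's multiplier satisfies `alpha_i = C` exactly when its functional
   margin `y_i (w·x_i + b) < 1` — these margin violators are the cells the
   panel cannot explain.  They form the acquisition pool.
3. **Acquire a cell set `I`.** Either a fresh sample of `c` violators
   (*min-complexity*, cheapest compute) or a cumulative set that reuses
   previously acquired violators first (*min-cell*, fewest unique cells
   ever measured).  Sampling is uniform or class-balanced.
4. **Rotate the margin.** For every candidate gene `j`, refit the SVM on
   `(I, J + {j})` and measure the rotation angle between the new weight
   vector and the current weights zero-padded into the extra dimension:
   `theta_j = arccos( <w_j, w_pad> / (||w_j|| ||w_pad||) )`, summed over
   one-vs-rest components.  The gene that rotates the margin most — the
   largest expected model change — joins the panel.

The loop stops at the target panel size `k` or when the pool empties.  Only
two dense blocks are ever materialized: `N x |J|` (all cells, panel genes)
and `|I| x M` (cell set, all genes), so memory stays `O(N + M)` and the
matrix itself can live on disk.

## Worked example

A planted-marker simulation (600 cells, 1,000 genes, 3 classes, 5 markers
per class at fold change 6, negative-binomial noise, 30% dropout):

```python
from activesvm import ActiveSVM, PlantedSpec, generate_planted

store, labels, truth = generate_planted(PlantedSpec(seed=0))
model = ActiveSVM(store, labels, k=20, c=20, strategy="min_complexity",
                  preprocess="colnorm_log_l2", seed=0)
res = model.fit()
print(res.summary())
print("marker recall in first 20:", res.marker_recovery(truth, 20))
```

```
Active SVM gene panel selection
==============================================
strategy: min_complexity sampling: random
genes selected: 20     status: completed
final test accuracy: 0.9583 (+/- 0.0358, 95% CI)
unique training cells analyzed: 276
----------------------------------------------
 iteration gene_name  rotation_angle  train_accuracy  test_accuracy  unique_cells
         0    g00000             NaN          0.3521         0.3583            20
         1    g00109          4.7438          0.4146         0.4417            36
 ...
        13    g00967          1.3408          0.8750         0.9167           216
 ...
        19    g00424          1.3189          0.9229         0.9583           276

marker recall in first 20: 0.8
```

Reading the output: each row adds one gene; `rotation_angle` is the winning
margin-rotation score (radians, summed over the 3 one-vs-rest classifiers),
and accuracy is measured on a held-out 20% of cells.  Twenty genes out of
1,000 recover 95.8% test accuracy (chance is 33%), 12 of the 15 planted
markers appear in the panel, and only 276 of the 480 training cells were
ever read at full transcriptome width — the min-cell strategy reduces that
further.  `res.correlation_matrix()` gives the pairwise Pearson matrix of
the panel and `res.plot_accuracy()` the accuracy/unique-cell curves.

The same run from a shell:

```bash
activesvm simulate --cells 600 --genes 1000 --classes 3 --seed 0 --out data/
activesvm run --matrix data/matrix.mtx --labels data/labels.csv \
    --strategy min_complexity --k 20 --cells-per-iter 20 --seed 0 --out out/
activesvm baseline --method correlation --matrix data/matrix.mtx \
    --labels data/labels.csv --k 20 --out out-corr/
```

`out/` receives `genes.csv` (the ranked panel), `curves.csv` (per-iteration
records), `correlation.csv` and `run.json`.

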