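"""Orchestration of the iterative gene-panel construction.

Each iteration: (1) fit the *step* SVM on all training cells restricted to
the current panel J and record train/test accuracy; (2) build the pool of
margin violators among training cells; (3) acquire this iteration's cell set
under the configured strategy; (4) score all remaining genes by margin
rotation on that cell set and append the winner to J.  The loop ends when
|J| reaches the target k or the pool empties (every training cell classifies
cleanly — nothing left to learn from).

All randomness flows from a single root seed split into named streams
(train/test split, bootstrap sample, per-iteration cell sampling), so a run
is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionStore, LabelVector
from .preprocess import SplitResult, split_train_test
from .selection import (SelectionState, build_pool, sample_min_complexity,
                        select_first_gene, select_next_gene, update_min_cell)
from .svm import fit_linear_svm, margin_report, predict_and_score

logger = logging.getLogger("activesvm")

STRATEGIES = ("min_cell", "min_complexity")
SAMPLING_MODES = ("random", "balanced")
POOL_CRITERIA = ("violators", "violators_or_margin")


@dataclass
class RunConfig:
    """Knobs of one panel-construction run."""

    k: int = 20                        # target panel size
    c: int = 20                        # cells acquired per iteration
    C: float = 1.0                     # SVM regularization
    strategy: str = "min_complexity"
    sampling: str = "random"
    pool_criterion: str = "violators"
    preprocess: str = "none"           # applied by the pipeline, echoed here
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.c < 1:
            raise ValueError("c must be at least 1")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.sampling not in SAMPLING_MODES:
            raise ValueError(f"sampling must be one of {SAMPLING_MODES}")
        if self.pool_criterion not in POOL_CRITERIA:
            raise ValueError(f"pool_criterion must be one of {POOL_CRITERIA}")


@dataclass
class IterationRecord:
    iteration: int
    gene_index: int
    gene_name: str
    rotation_angle: float      # NaN for the bootstrap pick
    train_accuracy: float
    test_accuracy: float
    cell_set_size: int         # |I| used to select this gene
    unique_cells: int          # distinct training cells touched so far


@dataclass
class RunResult:
    gene_indices: np.ndarray
    gene_names: list
    records: list
    final_state: object
    status: str                 # "completed" | "pool_exhausted" | "empty"
    config: RunConfig
    split: SplitResult = None

    @property
    def curves(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    @property
    def unique_cells_total(self) -> int:
        return self.records[-1].unique_cells if self.records else 0


def _bootstrap_cells(rng, train_idx, labels, c, max_tries: int = 100) -> np.ndarray:
    """Seeded initial cell sample; resampled until two classes are present."""
    n = min(c, train_idx.size)
    for attempt in range(max_tries):
        cells = np.sort(rng.choice(train_idx, size=n, replace=False))
        if np.unique(labels[cells]).size >= 2:
            if attempt:
                logger.warning("bootstrap resampled %d times for class coverage", attempt)
            return cells
        n = min(n * 2, train_idx.size)
    raise RuntimeError("could not draw a multi-class bootstrap sample")


def run_activesvm(config: RunConfig, store: ExpressionStore,
                  labels: LabelVector) -> RunResult:
    """Run the full iterative procedure on preprocessed data."""
    if len(labels) != store.n_cells:
        raise ValueError("labels length does not match store cells")
    y = labels.labels

    ss = np.random.SeedSequence(config.seed)
    seed_split, seed_boot, seed_sample = ss.spawn(3)
    split = split_train_test(store.n_cells, labels, config.train_fraction,
                             seed=seed_split)
    train_idx, test_idx = split.train_cell_indices, split.test_cell_indices

    if config.k == 0:
        return RunResult(np.array([], dtype=np.intp), [], [], None,
                         "empty", config, split)

    rng_sample = np.random.default_rng(seed_sample)
    boot_cells = _bootstrap_cells(np.random.default_rng(seed_boot),
                                  train_idx, y, config.c)
    sel = SelectionState()
    sel.record_use(boot_cells)
    first = select_first_gene(store, y, boot_cells, config.C)
    J = [first]
    pending_angle = float("nan")
    pending_cellset = boot_cells.size

    records: list[IterationRecord] = []
    status = "completed"
    state = None
    while True:
        train_block = store.fetch_block(train_idx, np.asarray(J))
        state = fit_linear_svm(train_block, y[train_idx], config.C,
                               genes=np.asarray(J))
        train_acc = predict_and_score(state, train_block, y[train_idx])
        test_block = store.fetch_block(test_idx, np.asarray(J))
        test_acc = predict_and_score(state, test_block, y[test_idx])
        del test_block
        records.append(IterationRecord(
            iteration=len(J) - 1, gene_index=J[-1],
            gene_name=str(store.gene_names[J[-1]]),
            rotation_angle=pending_angle, train_accuracy=train_acc,
            test_accuracy=test_acc, cell_set_size=pending_cellset,
            unique_cells=sel.n_unique_cells))
        logger.info("iter=%d gene=%s angle=%.4f train=%.4f test=%.4f |I|=%d unique=%d",
                    len(J) - 1, store.gene_names[J[-1]], pending_angle,
                    train_acc, test_acc, pending_cellset, sel.n_unique_cells)
        if len(J) >= config.k or len(J) >= store.n_genes:
            break

        report = margin_report(state, train_block, y[train_idx])
        del train_block
        pool_local = build_pool(report, config.pool_criterion)
        if pool_local.size == 0:
            status = "pool_exhausted"
            logger.info("pool empty after %d genes; stopping early", len(J))
            break
        S = train_idx[pool_local]

        if config.strategy == "min_complexity":
            cell_set = sample_min_complexity(S, config.c, config.sampling,
                                             y, rng_sample)
            sel.record_use(cell_set)
        else:
            sel = update_min_cell(S, sel, config.c, config.sampling,
                                  y, rng_sample)
            cell_set = sel.I
        if np.unique(y[cell_set]).size < 2:
            status = "pool_exhausted"
            logger.info("single-class cell set after %d genes; stopping early", len(J))
            break

        gene, scores = select_next_gene(store, y, np.asarray(J), cell_set,
                                        config.C)
        pending_angle = next(s.angle for s in scores if s.gene == gene)
        pending_cellset = cell_set.size
        J.append(gene)

    gene_indices = np.asarray(J, dtype=np.intp)
    return RunResult(gene_indices,
                     [str(store.gene_names[j]) for j in gene_indices],
                     records, state, status, config, split)


def proportion_ci(error_rate: float, n: int, z: float = 1.96) -> float:
    """Half-width of the normal-approximation proportion confidence interval."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    return float(z * np.sqrt(error_rate * (1.0 - error_rate) / n))


def correlation_matrix(store: ExpressionStore, gene_set) -> pd.DataFrame:
    """Pairwise Pearson correlations of the given genes over all cells.

    Constant genes get coefficient 0 against everything (with a warning);
    the diagonal is always 1.
    """
    import warnings

    genes = np.asarray(gene_set)
    if genes.dtype.kind in "UO":
        names = [str(g) for g in genes]
        idx = store.gene_index(names)
    else:
        idx = genes.astype(np.intp)
        names = [str(store.gene_names[j]) for j in idx]
    if idx.size < 2:
        raise ValueError("need at least two genes")
    block = store.fetch_block(None, idx)
    constant = block.std(axis=0) == 0
    if np.any(constant):
        warnings.warn(f"constant genes in correlation matrix: "
                      f"{[names[i] for i in np.flatnonzero(constant)]}",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(block, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def write_outputs(result: RunResult, outdir, store: ExpressionStore = None) -> None:
    """Write genes.csv, curves.csv, run.json (and correlation.csv if possible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = pd.DataFrame({
        "rank": np.arange(1, len(result.gene_names) + 1),
        "gene": result.gene_names,
        "rotation_angle": [r.rotation_angle for r in result.records],
    })
    genes.to_csv(outdir / "genes.csv", index=False)
    result.curves.to_csv(outdir / "curves.csv", index=False)
    if store is not None and len(result.gene_indices) >= 2:
        correlation_matrix(store, result.gene_indices).to_csv(outdir / "correlation.csv")
    payload = {"config": asdict(result.config), "status": result.status,
               "n_genes_selected": len(result.gene_names),
               "unique_cells": result.unique_cells_total}
    (outdir / "run.json").write_text(json.dumps(payload, indent=2) + "\n")
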