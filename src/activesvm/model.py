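"""Model/Results facade over the iterative procedure.

`ActiveSVM` is constructed from data (a store or a DataFrame) plus run
parameters; `fit()` executes the full loop and returns an
:class:`ActiveSVMResults` carrying the selected panel, the per-iteration
accuracy curves, the final classifier and a ``summary()`` table.  Plotting
and post-hoc diagnostics (correlation matrix, marker recovery against a
planted truth) hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DenseStore, ExpressionStore, LabelVector
from .driver import (RunConfig, RunResult, correlation_matrix, proportion_ci,
                     run_activesvm, write_outputs)
from .preprocess import apply_preset, drop_empty
from .synthetic import SyntheticTruth, marker_recovery


class ActiveSVM:
    """Active-learning minimal marker-panel selector.

    Parameters mirror :class:`~activesvm.driver.RunConfig`; ``preprocess``
    names the preprocessing preset applied to the raw store before the run
    (``colnorm_log_l2``, ``l2_only`` or ``none``).
    """

    def __init__(self, store: ExpressionStore, labels: LabelVector, *,
                 k: int = 20, c: int = 20, C: float = 1.0,
                 strategy: str = "min_complexity", sampling: str = "random",
                 pool_criterion: str = "violators",
                 preprocess: str = "colnorm_log_l2",
                 train_fraction: float = 0.8, seed: int = 0,
                 drop_empty_axes: bool = True):
        if not isinstance(labels, LabelVector):
            labels = LabelVector(np.asarray(labels))
        if len(labels) != store.n_cells:
            raise ValueError("labels length does not match store cells")
        self.raw_store = store
        self.config = RunConfig(k=k, c=c, C=C, strategy=strategy,
                                sampling=sampling, pool_criterion=pool_criterion,
                                preprocess=preprocess,
                                train_fraction=train_fraction, seed=seed)
        if drop_empty_axes:
            store, kept_genes, kept_cells = drop_empty(store)
            labels = LabelVector(labels.labels[kept_cells])
            self.kept_gene_indices = kept_genes
            self.kept_cell_indices = kept_cells
        else:
            self.kept_gene_indices = np.arange(store.n_genes)
            self.kept_cell_indices = np.arange(store.n_cells)
        self.store = apply_preset(store, preprocess)
        self.labels = labels

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels, **kwargs) -> "ActiveSVM":
        """Build from a cells x genes DataFrame (index = cells, columns = genes)."""
        store = DenseStore(frame.to_numpy(dtype=float),
                           list(frame.columns), [str(i) for i in frame.index])
        return cls(store, labels, **kwargs)

    def fit(self) -> "ActiveSVMResults":
        result = run_activesvm(self.config, self.store, self.labels)
        return ActiveSVMResults(self, result)


class ActiveSVMResults:
    """Selected panel, accuracy curves and final classifier of one run."""

    def __init__(self, model: ActiveSVM, result: RunResult):
        self.model = model
        self.run = result
        self.selected_genes = list(result.gene_names)
        self.selected_gene_indices = result.gene_indices
        self.status = result.status
        self.final_state = result.final_state

    @property
    def curves(self) -> pd.DataFrame:
        """Per-iteration table: gene, rotation angle, accuracies, cell usage."""
        return self.run.curves

    @property
    def test_accuracy(self) -> float:
        return self.run.records[-1].test_accuracy if self.run.records else float("nan")

    @property
    def unique_cells(self) -> int:
        return self.run.unique_cells_total

    def accuracy_ci(self, z: float = 1.96) -> float:
        """Proportion-CI half-width of the final test error."""
        n_test = self.run.split.test_cell_indices.size
        return proportion_ci(1.0 - self.test_accuracy, n_test, z)

    def correlation_matrix(self) -> pd.DataFrame:
        return correlation_matrix(self.model.store, self.selected_gene_indices)

    def marker_recovery(self, truth: SyntheticTruth, first: int | None = None) -> float:
        """Recall of planted markers within the (optionally truncated) panel."""
        idx = self.selected_gene_indices[:first]
        original = self.model.kept_gene_indices[idx]
        return marker_recovery(original, truth)

    def summary(self) -> str:
        cfg = self.run.config
        lines = [
            "Active SVM gene panel selection",
            "=" * 46,
            f"strategy: {cfg.strategy:<14} sampling: {cfg.sampling}",
            f"genes selected: {len(self.selected_genes):<6} status: {self.status}",
            f"final test accuracy: {self.test_accuracy:.4f} "
            f"(+/- {self.accuracy_ci():.4f}, 95% CI)",
            f"unique training cells analyzed: {self.unique_cells}",
            "-" * 46,
        ]
        table = self.curves[["iteration", "gene_name", "rotation_angle",
                             "train_accuracy", "test_accuracy", "unique_cells"]]
        lines.append(table.to_string(index=False,
                                     float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Test accuracy and unique-cell usage versus panel size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curves = self.curves
        ngenes = curves["iteration"] + 1
        ax.plot(ngenes, curves["test_accuracy"], marker="o", label="test accuracy")
        ax.set_xlabel("genes selected")
        ax.set_ylabel("test accuracy")
        ax2 = ax.twinx()
        ax2.plot(ngenes, curves["unique_cells"], color="gray", ls="--",
                 label="unique cells")
        ax2.set_ylabel("unique cells analyzed")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="lower right")
        return ax

    def save(self, outdir) -> None:
        write_outputs(self.run, outdir, store=self.model.store)
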