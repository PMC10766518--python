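"""Comparison gene selectors run under the iterative protocol.

Each method iterates like the active procedure — draw ``c`` cells uniformly
at random, score every unselected gene against the labels on those cells,
append the argmax — but without any active learning: the cells are not chosen
by classification difficulty.  Methods:

* ``correlation`` — max over classes of |Pearson r| against the one-vs-rest
  class indicator;
* ``mutual_information`` — plug-in mutual information after equal-width
  binning of expression values;
* ``chi2`` — classic chi-squared statistic of non-negative per-class feature
  totals;
* ``tree_importance`` — impurity importance of the candidate in a shallow
  decision tree refit on selected + candidate genes;
* ``random`` — uniformly drawn unselected genes (the floor any selector
  should beat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.metrics import mutual_info_score
from sklearn.tree import DecisionTreeClassifier

from .data import ExpressionStore

METHODS = ("correlation", "mutual_information", "chi2", "tree_importance", "random")


@dataclass
class BaselineConfig:
    method: str
    k: int = 20
    c: int = 20
    seed: int = 0
    mi_bins: int = 10
    tree_depth: int = 10

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.k < 1 or self.c < 1:
            raise ValueError("k and c must be at least 1")


def score_gene(method: str, values: np.ndarray, labels: np.ndarray,
               mi_bins: int = 10, tree_depth: int = 10, seed: int = 0,
               selected_block: np.ndarray | None = None) -> float:
    """Score one gene's expression against the labels; constants score 0."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if np.ptp(values) == 0.0:
        return 0.0
    if method == "correlation":
        best = 0.0
        for z in np.unique(labels):
            ind = (labels == z).astype(np.float64)
            if np.ptp(ind) == 0.0:
                continue
            r = np.corrcoef(values, ind)[0, 1]
            best = max(best, abs(float(r)))
        return best
    if method == "mutual_information":
        edges = np.linspace(values.min(), values.max(), mi_bins + 1)
        binned = np.clip(np.digitize(values, edges[1:-1]), 0, mi_bins - 1)
        return float(mutual_info_score(binned, labels))
    if method == "chi2":
        if np.any(values < 0):
            raise ValueError("chi2 requires non-negative values")
        stat, _ = sk_chi2(values[:, None], labels)
        return float(stat[0])
    if method == "tree_importance":
        X = values[:, None] if selected_block is None \
            else np.column_stack([selected_block, values])
        tree = DecisionTreeClassifier(max_depth=tree_depth, random_state=seed)
        tree.fit(X, labels)
        return float(tree.feature_importances_[-1])
    raise ValueError(f"unknown scoring method {method!r}")


def baseline_select(config: BaselineConfig, store: ExpressionStore, labels,
                    train_indices=None) -> np.ndarray:
    """Greedy iterative selection under the random-cell-sampling protocol.

    Returns exactly ``min(k, n_genes)`` unique gene indices.  With fixed seed
    the list is reproducible; ties break to the smallest gene index.
    """
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    pool = np.arange(store.n_cells) if train_indices is None \
        else np.asarray(train_indices, dtype=np.intp)
    rng = np.random.default_rng(config.seed)
    selected: list[int] = []
    k = min(config.k, store.n_genes)

    while len(selected) < k:
        remaining = np.setdiff1d(np.arange(store.n_genes), selected)
        if config.method == "random":
            selected.append(int(rng.choice(remaining)))
            continue
        cells = _multi_class_sample(rng, pool, y, min(config.c, pool.size))
        block = store.fetch_block(cells, remaining)
        ysub = y[cells]
        if config.method == "tree_importance" and selected:
            sel_block = store.fetch_block(cells, np.asarray(selected))
        else:
            sel_block = None
        best_gene, best_score = -1, -np.inf
        for pos, j in enumerate(remaining):  # ascending: ties keep smallest
            s = score_gene(config.method, block[:, pos], ysub,
                           mi_bins=config.mi_bins, tree_depth=config.tree_depth,
                           seed=config.seed, selected_block=sel_block)
            if s > best_score:
                best_gene, best_score = int(j), s
        selected.append(best_gene)
    return np.asarray(selected, dtype=np.intp)


def _multi_class_sample(rng, pool, y, c, max_tries: int = 100) -> np.ndarray:
    """Uniform cell sample, redrawn if it collapses to a single class."""
    for _ in range(max_tries):
        cells = np.sort(rng.choice(pool, size=c, replace=False))
        if np.unique(y[cells]).size >= 2:
            return cells
    raise RuntimeError("could not draw a multi-class cell sample")
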