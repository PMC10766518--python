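"""Planted-marker count simulator for end-to-end testing and calibration.

Emulates class-structured scRNA-seq counts: every gene is negative-binomial
background noise with mean ``mu0`` and dispersion ``phi`` (variance
``mu + phi * mu^2``), except that each class owns a disjoint set of *marker*
genes whose mean is lifted to ``fold_change * mu0`` in that class's cells.
A Bernoulli dropout mask zeroes a fraction of all entries, mimicking
capture inefficiency.  The planted marker indices are returned as ground
truth so recovery of the panel can be scored.

This is a deliberately simple emulation: there is no library-size variation,
batch structure, or correlated background modules beyond the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DenseStore, LabelVector


@dataclass
class PlantedSpec:
    """Generator parameters (defaults give a comfortably learnable problem)."""

    n_cells: int = 600
    n_genes: int = 1000
    n_classes: int = 3
    markers_per_class: int = 5
    proportions: tuple = None        # default: equal classes
    fold_change: float = 6.0         # marker mean multiplier, > 1
    mu0: float = 2.0                 # background NB mean
    dispersion: float = 0.5          # phi in var = mu + phi mu^2
    dropout: float = 0.3             # Bernoulli zeroing probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_classes * self.markers_per_class > self.n_genes:
            raise ValueError("more marker genes than genes available")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be at least 1 (1 = no signal)")
        if self.mu0 <= 0 or self.dispersion <= 0:
            raise ValueError("mu0 and dispersion must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        if self.proportions is None:
            self.proportions = tuple([1.0 / self.n_classes] * self.n_classes)
        if len(self.proportions) != self.n_classes:
            raise ValueError("one proportion per class required")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("class proportions must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted marker indices per class and the class of every cell."""

    markers_by_class: dict
    cell_classes: np.ndarray

    @property
    def all_markers(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.markers_by_class.values())))


def generate_planted(spec: PlantedSpec):
    """Draw one planted-marker dataset.

    Returns ``(store, labels, truth)`` where the store holds raw counts in a
    dense in-memory backing.  Identical seeds give identical matrices.
    """
    rng = np.random.default_rng(spec.seed)

    # deterministic class sizes from proportions, remainder to the last class
    sizes = [int(round(p * spec.n_cells)) for p in spec.proportions]
    sizes[-1] = spec.n_cells - sum(sizes[:-1])
    if min(sizes) < 1:
        raise ValueError("a class received no cells; adjust proportions")
    labels = rng.permutation(np.repeat(np.arange(spec.n_classes), sizes))

    marker_pool = rng.permutation(spec.n_genes)[: spec.n_classes * spec.markers_per_class]
    markers_by_class = {
        z: np.sort(marker_pool[z * spec.markers_per_class:(z + 1) * spec.markers_per_class])
        for z in range(spec.n_classes)
    }

    mean = np.full((spec.n_cells, spec.n_genes), spec.mu0)
    for z, genes in markers_by_class.items():
        mean[np.ix_(labels == z, genes)] = spec.fold_change * spec.mu0

    r = 1.0 / spec.dispersion                       # NB number of failures
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.float64)
    if spec.dropout > 0:
        counts *= rng.random(counts.shape) >= spec.dropout

    gene_names = [f"g{j:05d}" for j in range(spec.n_genes)]
    cell_names = [f"c{i:05d}" for i in range(spec.n_cells)]
    store = DenseStore(counts, gene_names, cell_names)
    truth = SyntheticTruth(markers_by_class=markers_by_class, cell_classes=labels)
    return store, LabelVector(labels), truth


def marker_recovery(selected_genes, truth: SyntheticTruth) -> float:
    """Fraction of all planted markers present in the selected gene set."""
    markers = truth.all_markers
    selected = np.asarray(selected_genes)
    return float(np.intersect1d(selected, markers).size / markers.size)
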