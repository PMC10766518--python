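"""Cell acquisition strategies and margin-rotation gene scoring.

Gene selection works by *expected model change*: for every candidate gene j
not yet in the panel J, a fresh ``|J|+1``-dimensional SVM is fitted on the
current cell set I, and the candidate is scored by how far its weight vector
rotates away from the current ``|J|``-dimensional weight (zero-padded into
the new dimension).  The rotation angle is

    theta_j = arccos( <w_j, w_padded> / (||w_j|| ||w_padded||) )

summed over the one-vs-rest class components for multiclass problems.  The
gene with the maximum angle is selected.

Cell acquisition offers two strategies: *min-complexity* draws a fresh
fixed-size sample of margin violators each iteration, while *min-cell* reuses
previously acquired violators with highest priority and only tops the
accumulated set up with new cells, minimizing the total number of unique
cells touched.  Either can sample uniformly or with class-balanced
allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionStore
from .svm import MarginReport, fit_hinge_primal


@dataclass
class SelectionState:
    """Accumulated gene panel and cell set with per-cell use counts."""

    J: list = field(default_factory=list)            # ordered selected genes
    use_counts: dict = field(default_factory=dict)   # training-cell index -> uses
    iteration: int = 0

    @property
    def I(self) -> np.ndarray:
        """Accumulated cell set, ascending order."""
        return np.array(sorted(self.use_counts), dtype=np.intp)

    @property
    def n_unique_cells(self) -> int:
        return len(self.use_counts)

    def record_use(self, cells) -> None:
        for i in np.asarray(cells, dtype=np.intp):
            self.use_counts[int(i)] = self.use_counts.get(int(i), 0) + 1


@dataclass(frozen=True)
class RotationScore:
    gene: int
    angle: float  # radians; in [0, pi] per class component, summed over classes


def build_pool(report: MarginReport, criterion: str = "violators") -> np.ndarray:
    """Indices (into the report's cell order) eligible for acquisition."""
    return np.flatnonzero(report.eligible(criterion))


def balanced_allocation(candidates_by_class, c_prime: int) -> list[int]:
    """Per-class sample counts for a budget of ``c_prime`` cells.

    ``candidates_by_class`` must be ordered by ascending candidate count.
    Classes small enough to fit within an equal share of the remaining budget
    are taken whole; larger classes receive the floored equal share, with the
    remainder flowing to the later (larger) classes.  The total equals
    ``min(c_prime, total candidates)``.
    """
    if c_prime <= 0:
        raise ValueError("sampling budget must be positive")
    sizes = [len(s) for s in candidates_by_class]
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("classes must be ordered by ascending candidate count")
    Z = len(sizes)
    counts, taken = [], 0
    for z, size in enumerate(sizes):
        share = (c_prime - taken) / (Z - z)
        take = size if size <= share else int(np.floor(share))
        counts.append(take)
        taken += take
    return counts


def _group_by_class(cells: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    """Candidate cells per class, ordered by ascending group size (ties by class id)."""
    cells = np.asarray(cells, dtype=np.intp)
    groups = [cells[labels[cells] == z] for z in np.unique(labels[cells])]
    return sorted(groups, key=len)


def _balanced_sample(rng: np.random.Generator, cells: np.ndarray,
                     labels: np.ndarray, budget: int) -> np.ndarray:
    groups = _group_by_class(cells, labels)
    counts = balanced_allocation(groups, budget)
    picks = [g if n == len(g) else rng.choice(g, size=n, replace=False)
             for g, n in zip(groups, counts)]
    return np.sort(np.concatenate(picks)) if picks else np.array([], dtype=np.intp)


def sample_min_complexity(S, c: int, mode: str, labels, rng) -> np.ndarray:
    """Fresh cell set for this iteration: up to ``c`` cells sampled from S."""
    if c < 1:
        raise ValueError("c must be at least 1")
    S = np.asarray(S, dtype=np.intp)
    if S.size <= c:
        return np.sort(S)
    if mode == "random":
        return np.sort(rng.choice(S, size=c, replace=False))
    if mode == "balanced":
        return _balanced_sample(rng, S, labels, c)
    raise ValueError(f"unknown sampling mode {mode!r}")


def update_min_cell(S, state: SelectionState, c: int, mode: str, labels, rng) -> SelectionState:
    """Accumulate the min-cell strategy's cell set.

    With ``a`` eligible cells already in the accumulated set and ``b`` new
    ones, no cells are added when ``a >= c``; otherwise ``min(c - a, b)`` new
    cells are sampled from the unseen part of the pool.  Gene selection then
    uses the whole accumulated set.
    """
    if c < 1:
        raise ValueError("c must be at least 1")
    S = np.asarray(S, dtype=np.intp)
    in_I = np.isin(S, state.I)
    a = int(in_I.sum())
    new_candidates = S[~in_I]
    if a < c and new_candidates.size:
        budget = min(c - a, new_candidates.size)
        if mode == "random":
            added = rng.choice(new_candidates, size=budget, replace=False)
        elif mode == "balanced":
            added = _balanced_sample(rng, new_candidates, labels, budget)
        else:
            raise ValueError(f"unknown sampling mode {mode!r}")
        for i in np.asarray(added, dtype=np.intp):
            state.use_counts.setdefault(int(i), 0)
    # every accumulated cell participates in this iteration's gene selection
    state.record_use(state.I)
    state.iteration += 1
    return state


def margin_rotation_angle(w_prev: np.ndarray, w_cand: np.ndarray) -> float:
    """Angle between the candidate weight and the zero-padded previous weight.

    Returns 0 when either vector has zero norm (the added dimension carries
    no usable direction).  The cosine is clamped to [-1, 1] before arccos.
    """
    w_prev = np.asarray(w_prev, dtype=np.float64).ravel()
    w_cand = np.asarray(w_cand, dtype=np.float64).ravel()
    if w_cand.size != w_prev.size + 1:
        raise ValueError("candidate weight must have exactly one extra dimension")
    padded = np.concatenate([w_prev, [0.0]])
    n1, n2 = np.linalg.norm(padded), np.linalg.norm(w_cand)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    cos = float(np.clip(padded @ w_cand / (n1 * n2), -1.0, 1.0))
    return float(np.arccos(cos))


def multiclass_rotation(w_prev_per_class, w_cand_per_class) -> float:
    """Sum of per-class rotation angles (one-vs-rest components)."""
    if len(w_prev_per_class) != len(w_cand_per_class):
        raise ValueError("class components of the two states differ")
    return float(sum(margin_rotation_angle(wp, wc)
                     for wp, wc in zip(w_prev_per_class, w_cand_per_class)))


def rotation_between_states(prev: SVMState, cand: SVMState) -> float:
    if prev.n_classifiers != cand.n_classifiers or not np.array_equal(prev.classes, cand.classes):
        raise ValueError("class sets of the two SVM states differ")
    return multiclass_rotation(list(prev.coef), list(cand.coef))


def _ovr_signed_targets(yI: np.ndarray) -> list[np.ndarray]:
    """One signed +/-1 target per classifier: a single one for two classes,
    otherwise one one-vs-rest target per class (ascending class id)."""
    classes = np.unique(yI)
    if classes.size == 2:
        return [np.where(yI == classes[1], 1.0, -1.0)]
    return [np.where(yI == z, 1.0, -1.0) for z in classes]


def select_next_gene(store: ExpressionStore, labels, J, I, C: float,
                     candidate_genes=None, solver_tol: float = 1e-4,
                     max_iter: int = 20000):
    """Score every candidate gene by margin rotation and return the argmax.

    The reference weights come from a ``|J|``-dimensional SVM on the cell set
    ``(I, J)``; for each candidate j a fresh one-vs-rest SVM is fitted on
    ``(I, J + [j])`` and the rotation of its weights against the zero-padded
    reference is computed.  Both reference and candidates use the same
    hinge-loss solver so that the only difference between them is the added
    gene.  Ties break to the smallest gene index.  Returns ``(gene, scores)``.
    """
    J = np.asarray(J, dtype=np.intp)
    I = np.asarray(I, dtype=np.intp)
    if J.size < 1:
        raise ValueError("need at least one selected gene")
    if I.size < 2:
        raise ValueError("need at least two cells")
    if candidate_genes is None:
        candidate_genes = np.arange(store.n_genes)
    candidates = np.setdiff1d(np.asarray(candidate_genes, dtype=np.intp), J)
    if candidates.size == 0:
        raise ValueError("no candidate genes remaining")
    yI = np.asarray(labels)[I]
    if np.unique(yI).size < 2:
        raise ValueError("cell set contains a single class")

    cols = np.concatenate([J, candidates])
    block = store.fetch_block(I, cols)  # the |I| x M working matrix
    base = np.ascontiguousarray(block[:, :J.size])
    targets = _ovr_signed_targets(yI)
    ref_ws = [fit_hinge_primal(base, t, C, solver_tol, max_iter)[0]
              for t in targets]

    X = np.empty((I.size, J.size + 1), dtype=np.float64)
    X[:, :-1] = base
    best_gene, best_angle = -1, -np.inf
    scores = []
    for pos, j in enumerate(candidates):  # ascending j: ties keep smallest index
        col = block[:, J.size + pos]
        angle = 0.0
        if np.ptp(col) > 0.0:  # a constant gene adds no usable dimension
            X[:, -1] = col
            for w_ref, t in zip(ref_ws, targets):
                w_cand, _ = fit_hinge_primal(X, t, C, solver_tol, max_iter)
                angle += margin_rotation_angle(w_ref, w_cand)
        scores.append(RotationScore(gene=int(j), angle=angle))
        if angle > best_angle:
            best_gene, best_angle = int(j), angle
    return best_gene, scores


def select_first_gene(store: ExpressionStore, labels, initial_cells, C: float,
                      candidate_genes=None, solver_tol: float = 1e-4,
                      max_iter: int = 20000) -> int:
    """Bootstrap pick: the gene whose 1-D SVM best classifies the seed cells.

    The iterative loop needs an existing weight vector to rotate against;
    the first gene is chosen by exhaustive 1-D training accuracy instead.
    Ties break to the smallest gene index.
    """
    I = np.asarray(initial_cells, dtype=np.intp)
    yI = np.asarray(labels)[I]
    classes = np.unique(yI)
    if classes.size < 2:
        raise ValueError("initial cell sample contains a single class")
    candidates = np.arange(store.n_genes) if candidate_genes is None \
        else np.asarray(candidate_genes, dtype=np.intp)
    block = store.fetch_block(I, candidates)
    targets = _ovr_signed_targets(yI)
    best_gene, best_acc = -1, -np.inf
    for pos, j in enumerate(candidates):
        col = np.ascontiguousarray(block[:, pos:pos + 1])
        if np.ptp(col) == 0.0:  # constant gene cannot separate anything
            acc = 0.0
        else:
            dec = np.empty((I.size, len(targets)))
            for t_idx, t in enumerate(targets):
                w, b = fit_hinge_primal(col, t, C, solver_tol, max_iter)
                dec[:, t_idx] = col[:, 0] * w[0] + b
            if classes.size == 2:
                pred = np.where(dec[:, 0] >= 0, classes[1], classes[0])
            else:
                pred = classes[np.argmax(dec, axis=1)]
            acc = float(np.mean(pred == yI))
        if acc > best_acc:
            best_gene, best_acc = int(j), acc
    return best_gene
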