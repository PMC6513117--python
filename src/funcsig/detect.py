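"""Modularity optimization on filtered correlation matrices.

The objective is the correlation-matrix modularity

    Q(sigma) = (1/C_norm) * sum_ij [C_ij - <C_ij>] * delta(sigma_i, sigma_j)

where the null expectation ``<C>`` is realized spectrally: ``C - <C>`` is the
structural eigencomponent ``C_filtered`` of :mod:`funcsig.rmt` (the global
mode and the random bulk ARE the null).  The sum runs over all ordered pairs
including ``i = j``; the diagonal is constant across partitions and only
shifts the score.

Optimization is Louvain-style: randomized single-node sweeps to a local
optimum, aggregation of modules into super-nodes, repeat; then a
post-processing pass enforces stability under merging any pair of modules
and under dissolving any module with non-positive internal weight.  Merge
stability is what guarantees the sign contrast of the output: every pair of
returned modules has non-positive total inter-module weight, and every
non-singleton module has positive total internal weight — modules are
positively correlated inside and negatively correlated across.

The number of modules is never an input.  When the structural set is empty
(``B = 0``) the system is reported as a single non-significant module.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConvergenceError, InputError
from .rmt import FilteredDecomposition, filter_correlation
from .timeseries import ActivityRecording, CorrelationMatrix, pearson_correlation

_TOL = 1e-12


@dataclass
class Partition:
    """Unit-to-module assignment with its modularity score."""

    labels: np.ndarray
    n_modules: int
    modularity: float
    significant: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        k = self.labels.max() + 1 if self.labels.size else 0
        if k != self.n_modules or not np.array_equal(
            np.unique(self.labels), np.arange(self.n_modules)
        ):
            raise InputError("labels must be contiguous integers 0..n_modules-1")

    def module_members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.labels == m)

    def save(self, unit_ids: list[str], path: str | Path) -> None:
        pd.DataFrame({"unit_id": unit_ids, "module_id": self.labels}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ModularityMatrix:
    """The centered matrix ``B = C - <C>`` plus its normalization constant."""

    matrix: np.ndarray
    c_norm: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise InputError("modularity matrix must be square")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-8:
            raise InputError("modularity matrix must be symmetric")
        if self.c_norm <= 0:
            raise InputError("c_norm must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_filtered(
        cls, filt: FilteredDecomposition, source: CorrelationMatrix
    ) -> "ModularityMatrix":
        """Build the objective from a filtered decomposition.

        ``c_norm`` is the total weight of the ORIGINAL correlation matrix
        when positive (keeps Q dimensionless and comparable across samples),
        else N.  Any positive constant leaves the argmax unchanged.
        """
        total = float(source.values.sum())
        return cls(matrix=filt.c_filtered, c_norm=total if total > 0 else source.n_units)


@dataclass
class CoClassificationMatrix:
    """Frequency with which unit pairs share a module over repeated runs."""

    frequencies: np.ndarray
    n_runs: int

    @property
    def is_binary(self) -> bool:
        f = self.frequencies
        return bool(np.all((f < 1e-9) | (f > 1 - 1e-9)))


@dataclass
class HierarchyNode:
    """One level of the recursive module hierarchy."""

    partition: Partition
    depth: int
    unit_indices: np.ndarray
    children: dict[int, "HierarchyNode"] = field(default_factory=dict)

    def to_dict(self, unit_ids: list[str] | None = None) -> dict:
        ids = (
            [unit_ids[i] for i in self.unit_indices]
            if unit_ids is not None
            else self.unit_indices.tolist()
        )
        return {
            "depth": self.depth,
            "n_modules": self.partition.n_modules,
            "modularity": self.partition.modularity,
            "significant": self.partition.significant,
            "units": ids,
            "labels": self.partition.labels.tolist(),
            "children": {str(m): c.to_dict(unit_ids) for m, c in self.children.items()},
        }


# ---------------------------------------------------------------------------
# Louvain engine


@njit(cache=True)
def _sweep(b: np.ndarray, labels: np.ndarray, order: np.ndarray) -> bool:
    """Single-node moves to a local optimum; labels edited in place.

    Moving node i from module a to c changes the within-module weight by
    s(c) - (s(a) - B_ii), with s(m) the weight from i to module m.  Ties
    keep the lowest candidate module index; staying wins exact ties.
    """
    n = b.shape[0]
    s = np.zeros(n)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for oi in range(n):
            i = order[oi]
            for j in range(n):
                s[labels[j]] += b[i, j]
            a = labels[i]
            best_c = a
            best_val = s[a] - b[i, i]
            for c in range(n):
                if c != a and s[c] > best_val + 1e-12:
                    best_val = s[c]
                    best_c = c
            if best_c != a:
                labels[i] = best_c
                improved = True
                moved_any = True
            for c in range(n):
                s[c] = 0.0
    return moved_any


def _compact(labels: np.ndarray) -> np.ndarray:
    return np.unique(labels, return_inverse=True)[1].astype(np.int64)


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((len(labels), k))
    m[np.arange(len(labels)), labels] = 1.0
    return m


def _block_sums(b: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    m = _one_hot(labels, k)
    return m.T @ b @ m


def _within_sum(b: np.ndarray, labels: np.ndarray) -> float:
    k = int(labels.max()) + 1
    return float(np.trace(_block_sums(b, labels, k)))


def _louvain_once(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One randomized Louvain run: local moves + aggregation to convergence."""
    n = b.shape[0]
    assign = np.arange(n, dtype=np.int64)
    b_cur = np.ascontiguousarray(b)
    while True:
        m = b_cur.shape[0]
        labels = np.arange(m, dtype=np.int64)
        order = rng.permutation(m).astype(np.int64)
        _sweep(b_cur, labels, order)
        labels = _compact(labels)
        k = int(labels.max()) + 1
        assign = labels[assign]
        if k == m:
            break
        oh = _one_hot(labels, k)
        b_cur = np.ascontiguousarray(oh.T @ b_cur @ oh)
    return assign


def _stabilize(
    b: np.ndarray, labels: np.ndarray, rng: np.random.Generator, max_iter: int = 500
) -> np.ndarray:
    """Enforce stability under pairwise merges, dissolution and node moves.

    Each step strictly increases the within-module weight, so the loop
    terminates; ``max_iter`` is a safety valve only.
    """
    labels = _compact(labels)
    n = len(labels)
    for _ in range(max_iter):
        k = int(labels.max()) + 1
        e = _block_sums(b, labels, k)
        # merge the most positively coupled module pair, if any
        if k > 1:
            off = e.copy()
            np.fill_diagonal(off, -np.inf)
            a, c = np.unravel_index(int(np.argmax(off)), off.shape)
            if off[a, c] > _TOL:
                labels[labels == max(a, c)] = min(a, c)
                labels = _compact(labels)
                continue
        # dissolve a non-singleton module whose internal weight is not positive
        sizes = np.bincount(labels, minlength=k)
        diag_by_mod = np.bincount(labels, weights=np.diag(b), minlength=k)
        bad = np.flatnonzero(
            (sizes > 1) & (np.diag(e) <= _TOL) & (diag_by_mod - np.diag(e) > _TOL)
        )
        if bad.size:
            members = np.flatnonzero(labels == bad[0])
            labels[members] = k + np.arange(len(members))
            labels = _compact(labels)
            _sweep(b, labels, rng.permutation(n).astype(np.int64))
            labels = _compact(labels)
            continue
        # node-level refinement on the original matrix
        if _sweep(b, labels, rng.permutation(n).astype(np.int64)):
            labels = _compact(labels)
            continue
        return _compact(labels)
    return _compact(labels)


def modularity_score(b: ModularityMatrix, p: Partition | np.ndarray) -> float:
    """Q(sigma) = (1/c_norm) * sum over same-module ordered pairs of B_ij."""
    labels = p.labels if isinstance(p, Partition) else np.asarray(p, dtype=int)
    if len(labels) != b.n:
        raise InputError("partition size does not match matrix")
    return _within_sum(b.matrix, labels) / b.c_norm


def optimize_partition(
    b: ModularityMatrix, seed: int = 0, n_restarts: int = 100
) -> Partition:
    """Maximize Q over partitions; best of ``n_restarts`` randomized runs.

    The returned partition is stable under single-node moves, under merging
    any pair of modules, and under dissolving any module (hence the sign
    contrast of the result).  A zero objective matrix — empty structural set
    — yields a single module flagged not significant.
    """
    n = b.n
    if not np.any(b.matrix):
        labels = np.zeros(n, dtype=int)
        return Partition(labels, 1, 0.0, significant=False)
    rng = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_w = -np.inf
    for _ in range(max(1, n_restarts)):
        labels = _louvain_once(b.matrix, rng)
        labels = _stabilize(b.matrix, labels, rng)
        w = _within_sum(b.matrix, labels)
        if w > best_w + _TOL:
            best_w, best_labels = w, labels
    assert best_labels is not None
    return Partition(
        labels=best_labels,
        n_modules=int(best_labels.max()) + 1,
        modularity=best_w / b.c_norm,
        significant=True,
    )


def co_classification(
    b: ModularityMatrix, n_runs: int, base_seed: int = 0
) -> CoClassificationMatrix:
    """Fraction of independent runs in which unit pairs share a module.

    Run r uses seed ``base_seed + r`` with a single restart, so the matrix
    reflects genuine run-to-run variability of the optimizer.
    """
    if n_runs < 1:
        raise InputError("n_runs must be >= 1")
    f = np.zeros((b.n, b.n))
    for r in range(n_runs):
        p = optimize_partition(b, seed=base_seed + r, n_restarts=1)
        f += p.labels[:, None] == p.labels[None, :]
    return CoClassificationMatrix(frequencies=f / n_runs, n_runs=n_runs)


def consensus_partition(
    f: CoClassificationMatrix,
    tau: float = 0.5,
    seed: int = 0,
    *,
    runs_per_iter: int = 12,
    max_iter: int = 30,
) -> Partition:
    """Iterated consensus over a co-classification matrix.

    Optimizes ``F - tau`` as the objective, recomputes the co-classification
    of repeated runs on it, and iterates until that matrix is binary (all
    runs agree); the agreed partition is returned.  Deterministic given
    ``seed``.
    """
    f_cur = f.frequencies
    n = f_cur.shape[0]
    for it in range(max_iter):
        b = ModularityMatrix(matrix=f_cur - tau, c_norm=float(n))
        cc = co_classification(b, runs_per_iter, base_seed=seed + it * runs_per_iter)
        if cc.is_binary:
            return optimize_partition(b, seed=seed + it * runs_per_iter, n_restarts=1)
        f_cur = cc.frequencies
    dev = float(np.max(np.minimum(f_cur, 1 - f_cur)))
    raise ConvergenceError(
        f"consensus did not converge in {max_iter} iterations "
        f"(max co-classification ambiguity {dev:.3f}); try a different tau"
    )


# ---------------------------------------------------------------------------
# Hierarchical recursion


def detect_hierarchy(
    rec: ActivityRecording,
    max_depth: int,
    *,
    min_module_size: int = 10,
    seed: int = 0,
    n_restarts: int = 100,
    mode: str = "auto",
) -> HierarchyNode:
    """Recursive module detection on the original time series.

    Each module's units are re-extracted from the ORIGINAL recording, their
    correlation matrix is re-filtered against a null with the submatrix's
    own (N', T) and global mode, and re-optimized.  Recursion stops when a
    module has no structural eigenvalues, is smaller than
    ``min_module_size``, or ``max_depth`` is reached.
    """
    if max_depth < 1:
        raise InputError("max_depth must be >= 1")

    def recurse(indices: np.ndarray, depth: int, node_seed: int) -> HierarchyNode:
        sub = rec.subset(indices)
        c = pearson_correlation(sub)
        filt, _, _ = filter_correlation(c, mode=mode)
        b = ModularityMatrix.from_filtered(filt, c)
        p = optimize_partition(b, seed=node_seed, n_restarts=n_restarts)
        node = HierarchyNode(partition=p, depth=depth, unit_indices=indices)
        if depth >= max_depth or not p.significant or p.n_modules < 2:
            return node
        for m in range(p.n_modules):
            members = indices[p.labels == m]
            if len(members) < max(min_module_size, 2):
                continue
            child = recurse(members, depth + 1, node_seed + 1009 * (m + 1))
            if child.partition.significant and child.partition.n_modules > 1:
                node.children[m] = child
        return node

    return recurse(np.arange(rec.n_units), 1, seed)


def hierarchy_labels(root: HierarchyNode, depth: int) -> np.ndarray:
    """Flatten a hierarchy into global module labels at a given depth."""
    if depth < 1:
        raise InputError("depth must be >= 1")
    pos = {int(u): i for i, u in enumerate(root.unit_indices)}
    labels = np.empty(len(root.unit_indices), dtype=int)
    counter = itertools.count()

    def visit(node: HierarchyNode, d: int) -> None:
        for m in range(node.partition.n_modules):
            members = node.unit_indices[node.partition.labels == m]
            child = node.children.get(m)
            if d < depth and child is not None:
                visit(child, d + 1)
            else:
                lab = next(counter)
                for u in members:
                    labels[pos[int(u)]] = lab

    visit(root, 1)
    return _compact(labels)


def save_hierarchy(root: HierarchyNode, unit_ids: list[str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(root.to_dict(unit_ids), indent=2, sort_keys=True))
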