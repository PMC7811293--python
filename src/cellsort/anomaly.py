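"""Isolation-forest cell-anomaly scoring, implemented from first principles.

An isolation tree recursively partitions a subsample of cells: each
internal node picks a uniformly random gene among those non-constant in the
node's cells and a split threshold uniform on that gene's (min, max) range;
recursion stops when a single cell remains or all remaining cells are
identical.  There is no height limit — trees grow to full isolation, so the
expected-depth correction applies only at leaves holding duplicate cells.

A cell's path length in a tree is the edge count from root to the leaf it
reaches, plus c(leaf size) at multi-cell leaves, where

    c(s) = 2 H(s−1) − 2 (s−1)/s ,   H(i) = ln(i) + γ  (γ ≈ 0.5772) ,

is the expected path length of an unsuccessful binary-search-tree lookup
(c(1) = 0, c(2) = 1 exactly).  The ensemble score of cell i over n trees of
subsample size ψ is

    s_i = − Σ_j h_ij / (c(ψ) · n) ,

so shorter average paths (easier isolation) give scores closer to 0: the
most anomalous cell has the largest s.  Ranking by s is a monotone
transform of the canonical isolation-forest score 2^{−E(h)/c(ψ)}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "IsolationTree",
    "IsolationForestModel",
    "expected_path_length",
    "fit_forest",
    "score_cells",
]

EULER_GAMMA = 0.5772156649


def expected_path_length(size: int) -> float:
    """c(s): average unsuccessful-search path length in a BST of s points."""
    if size < 0:
        raise ValueError("size must be >= 0")
    if size <= 1:
        return 0.0
    if size == 2:
        return 1.0
    h = np.log(size - 1) + EULER_GAMMA
    return 2.0 * h - 2.0 * (size - 1) / size


@dataclass
class _Node:
    # internal: gene split; leaf: gene = -1
    gene: int
    threshold: float
    left: "_Node | None" = None
    right: "_Node | None" = None
    count: int = 0
    depth: int = 0


@dataclass
class IsolationTree:
    root: _Node

    def path_lengths(self, data: np.ndarray) -> np.ndarray:
        """Path length h for each row of ``data`` (cells × genes)."""
        out = np.empty(data.shape[0])
        self._descend(self.root, np.arange(data.shape[0]), data, out)
        return out

    def _descend(self, node: _Node, idx: np.ndarray, data: np.ndarray,
                 out: np.ndarray) -> None:
        if node.gene < 0:
            adjust = expected_path_length(node.count) if node.count > 1 else 0.0
            out[idx] = node.depth + adjust
            return
        go_left = data[idx, node.gene] < node.threshold
        if go_left.any():
            self._descend(node.left, idx[go_left], data, out)
        if (~go_left).any():
            self._descend(node.right, idx[~go_left], data, out)


@dataclass
class IsolationForestModel:
    trees: list[IsolationTree]
    genes: list[str]
    psi: int
    n_trees: int
    c_psi: float
    seed: int


def _grow(data: np.ndarray, idx: np.ndarray, depth: int,
          rng: np.random.Generator) -> _Node:
    if len(idx) == 1:
        return _Node(gene=-1, threshold=0.0, count=1, depth=depth)
    sub = data[idx]
    spans = sub.max(axis=0) - sub.min(axis=0)
    splittable = np.flatnonzero(spans > 0)
    if len(splittable) == 0:  # identical cells: unsplittable duplicate leaf
        return _Node(gene=-1, threshold=0.0, count=len(idx), depth=depth)
    gene = int(rng.choice(splittable))
    lo, hi = sub[:, gene].min(), sub[:, gene].max()
    threshold = float(rng.uniform(lo, hi))
    go_left = data[idx, gene] < threshold
    if not go_left.any() or go_left.all():
        # threshold landed on the boundary; force a non-trivial split
        go_left = data[idx, gene] < hi
    node = _Node(gene=gene, threshold=threshold, depth=depth)
    node.left = _grow(data, idx[go_left], depth + 1, rng)
    node.right = _grow(data, idx[~go_left], depth + 1, rng)
    return node


def fit_forest(
    matrix: ExpressionMatrix,
    n_trees: int = 100,
    psi: int = 256,
    seed: int = 0,
) -> IsolationForestModel:
    """Grow an ensemble of isolation trees on random cell subsamples.

    Each tree trains on an independent uniform subsample of ψ cells drawn
    without replacement (ψ is clipped to the cell count with a warning if
    larger).  Trees grow until every cell is isolated or duplicates make
    further splits impossible.
    """
    data = matrix.values.to_numpy().T  # cells × genes
    n_cells = data.shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if psi > n_cells:
        warnings.warn(f"psi={psi} larger than cell count {n_cells}; clipped")
        psi = n_cells
    if psi < 2:
        raise ValueError("psi must be >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(n_trees) % (2**31)
    trees = []
    all_identical = bool((data == data[0]).all())
    if all_identical:
        warnings.warn("all cells identical; forest degenerates to single leaves")
    for ti in range(n_trees):
        rng = np.random.default_rng(int(seeds[ti]))
        idx = rng.choice(n_cells, size=psi, replace=False)
        trees.append(IsolationTree(_grow(data, idx, 0, rng)))
    return IsolationForestModel(
        trees=trees, genes=matrix.genes, psi=psi, n_trees=n_trees,
        c_psi=expected_path_length(psi), seed=seed,
    )


def score_cells(
    model: IsolationForestModel,
    matrix: ExpressionMatrix,
    subset=None,
) -> pd.DataFrame:
    """Anomaly score and rank for each cell (or a subset of cells).

    Returns a DataFrame indexed by cell with columns ``score`` (s_i, ≤ 0,
    closer to 0 = more anomalous), ``mean_path_length`` and ``rank``
    (1 = most anomalous; ties broken by cell order and logged).
    """
    if model.genes != matrix.genes:
        raise ValueError("gene space differs from the training data")
    cells = list(matrix.cells) if subset is None else list(subset)
    data = matrix.values[cells].to_numpy().T  # cells × genes
    total = np.zeros(data.shape[0])
    for tree in model.trees:
        total += tree.path_lengths(data)
    mean_h = total / model.n_trees
    scores = -total / (model.c_psi * model.n_trees)
    # rank 1 = most anomalous = largest s; stable sort keeps cell order on ties
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(cells), dtype=int)
    ranks[order] = np.arange(1, len(cells) + 1)
    n_tied = len(scores) - len(np.unique(scores))
    if n_tied:
        logging.getLogger("cellsort").info(
            "%d tied anomaly scores; ranks broken by cell order", n_tied
        )
    return pd.DataFrame(
        {"score": scores, "mean_path_length": mean_h, "rank": ranks}, index=cells
    )
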