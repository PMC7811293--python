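"""Synthetic data generators for end-to-end testing without downloads.

The generators emulate, at desk scale, the experimental designs used to
benchmark the annotators and the anomaly score: mixtures of planted cell
types in random fractions, spike-ins of a small number of phenotypically
shifted cells into a typical background, and random gene networks standing
in for a curated interaction network.

Counts follow a negative-binomial model: each gene draws a base mean from
a log-normal distribution (median 1 count/cell, log-sd 1) and a fixed
dispersion; a cell of planted type k multiplies the means of k's positive
markers by (1 + effect) and divides those of k's negative markers by the
same factor.  This reproduces the overdispersion and marker contrast that
drive the annotators, but not dropout structure, batch effects or
gene–gene correlation of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneNetwork, MarkerTable

__all__ = [
    "SyntheticTruth",
    "synth_marker_table",
    "synth_expression",
    "synth_anomaly_mixture",
    "synth_network",
]

DEFAULT_DISPERSION = 2.0     # NB size parameter r; var = mu + mu^2 / r
DEFAULT_LOG_MEAN_SD = 1.0    # log-sd of the per-gene base means
DEFAULT_EFFECT = 5.0         # marker fold-change is (1 + effect)
DEFAULT_ANOMALY_SHIFT = 9.0  # fold-change of the spike-in programme genes


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    cell_types: pd.Series                     # cell -> planted type (or "")
    anomaly: pd.Series                        # cell -> bool flag
    params: dict = field(default_factory=dict)


def synth_marker_table(
    n_types: int,
    markers_per_type: int = 5,
    n_shared: int = 0,
    n_negative: int = 0,
    seed: int = 0,
) -> MarkerTable:
    """Build a random marker table.

    Each type gets ``markers_per_type`` unique positive markers; then
    ``n_shared`` extra markers are each positive in two random types, and
    ``n_negative`` markers are each negative in one random type.
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    types = [f"Type{chr(65 + i) if i < 26 else i}" for i in range(n_types)]
    n_genes = n_types * markers_per_type + n_shared + n_negative
    genes = [f"G{i:04d}" for i in range(n_genes)]
    m = np.zeros((n_genes, n_types))
    row = 0
    for t in range(n_types):
        m[row: row + markers_per_type, t] = 1
        row += markers_per_type
    for _ in range(n_shared):
        pair = rng.choice(n_types, size=2, replace=False)
        m[row, pair] = 1
        row += 1
    for _ in range(n_negative):
        m[row, rng.integers(n_types)] = -1
        row += 1
    return MarkerTable(pd.DataFrame(m, index=genes, columns=types))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean matrix."""
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def synth_expression(
    table: MarkerTable,
    cells_per_type,
    n_background_genes: int = 100,
    effect: float = DEFAULT_EFFECT,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
):
    """Planted-type count matrix; returns (ExpressionMatrix, SyntheticTruth).

    ``cells_per_type`` maps each cell type (or lists, aligned with the
    table's types) to its number of cells.  Marker genes of the cell's
    type have their base means scaled by (1 + effect) if positive and
    1/(1 + effect) if negative; background genes are type-independent.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    types = table.cell_types
    if not isinstance(cells_per_type, dict):
        cells_per_type = dict(zip(types, cells_per_type))
    genes = list(table.genes) + [
        f"BG{i:04d}" for i in range(n_background_genes)
    ]
    base_mean = np.exp(rng.normal(0.0, DEFAULT_LOG_MEAN_SD, size=len(genes)))
    marker = table.entries.to_numpy()  # marker genes × types

    cells, cell_types = [], []
    blocks = []
    for t_idx, t in enumerate(types):
        n = int(cells_per_type.get(t, 0))
        if n == 0:
            continue
        mean = np.tile(base_mean[:, None], (1, n))
        sign = marker[:, t_idx]
        mean[: len(sign)][sign > 0] *= 1.0 + effect
        mean[: len(sign)][sign < 0] /= 1.0 + effect
        blocks.append(_nb_draw(rng, mean, dispersion))
        start = len(cells)
        cells += [f"{t}_c{start + i:05d}" for i in range(n)]
        cell_types += [t] * n
    if not blocks:
        raise ValueError("no cells requested")
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    truth = SyntheticTruth(
        cell_types=pd.Series(cell_types, index=cells),
        anomaly=pd.Series(False, index=cells),
        params={"effect": effect, "dispersion": dispersion, "seed": seed},
    )
    return ExpressionMatrix(values), truth


def synth_anomaly_mixture(
    base: ExpressionMatrix,
    n_anomalous: int = 20,
    shift: float = DEFAULT_ANOMALY_SHIFT,
    mode: str = "shifted",
    altered_fraction: float = 0.3,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
):
    """Spike anomalous cells into a base population.

    ``mode="shifted"`` draws the spike-ins from a distinct mean profile
    emulating a foreign cell type: a random ``altered_fraction`` of genes
    (the foreign type's own programme) have their base means — estimated
    from ``base`` — multiplied by (1 + shift), an equal fraction divided
    by (1 + shift), and the profile is rescaled to the base total so the
    spike-ins match the background sequencing depth.  ``shift`` therefore
    controls the phenotypic distance; ``shift=0`` reduces to the base
    profile.  ``mode="same"`` draws the spike-ins from the base profile
    itself (negative control; flags are then uncorrelated with
    expression).  Returns (ExpressionMatrix, SyntheticTruth).
    """
    if mode not in ("shifted", "same"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_anomalous >= base.n_cells:
        raise ValueError("n_anomalous must be small relative to the base")
    rng = np.random.default_rng(seed)
    gene_mean = base.values.mean(axis=1).to_numpy()
    if mode == "shifted" and shift > 0:
        order = rng.permutation(len(gene_mean))
        n_altered = int(altered_fraction * len(gene_mean))
        spike_mean = gene_mean.copy()
        spike_mean[order[:n_altered]] *= 1.0 + shift
        spike_mean[order[n_altered: 2 * n_altered]] /= 1.0 + shift
        spike_mean *= gene_mean.sum() / spike_mean.sum()
    else:
        spike_mean = gene_mean
    spikes = _nb_draw(
        rng, np.tile(spike_mean[:, None], (1, n_anomalous)), dispersion
    )
    spike_cells = [f"anom_c{i:04d}" for i in range(n_anomalous)]
    values = pd.concat(
        [base.values,
         pd.DataFrame(spikes, index=base.genes, columns=spike_cells)],
        axis=1,
    )
    flags = pd.Series(
        [False] * base.n_cells + [True] * n_anomalous, index=values.columns
    )
    truth = SyntheticTruth(
        cell_types=pd.Series("", index=values.columns),
        anomaly=flags,
        params={"shift": shift, "mode": mode,
                "altered_fraction": altered_fraction, "seed": seed},
    )
    return ExpressionMatrix(values), truth


def synth_network(genes, density: float = 0.1, seed: int = 0) -> GeneNetwork:
    """Erdős–Rényi undirected network on the given genes (no self-loops)."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    genes = list(genes)
    graph = nx.gnp_random_graph(len(genes), density, seed=int(seed))
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))
    graph.add_nodes_from(genes)
    return GeneNetwork(graph)
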