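"""Marker-table normalization and Hopfield attractor construction.

The raw marker table M (genes × cell types, entries in {−1, 0, +1}) is
normalized separately for positive and negative markers, first within each
cell type by its positive/negative marker count and then within each marker
gene by the number of types using it with that sign.  Markers unique to one
cell type thus keep a large weight, while promiscuous markers are
down-weighted.  Normalization is performed after restricting the table to
genes actually expressed in the dataset at hand, so per-type scales stay
comparable across datasets.

Hopfield attractor patterns are the columns of the normalized table with
negative entries set to zero (negative markers carry no weight in the
attractor dynamics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerTable

__all__ = ["AttractorSet", "normalize_and_restrict", "build_attractors"]


@dataclass
class AttractorSet:
    """Non-negative stored patterns, one per usable cell type.

    ``patterns`` is cell types × genes (each row is one pattern ξ̃ over the
    shared gene/node set).
    """

    patterns: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.patterns.to_numpy()
        if (arr < 0).any():
            raise ValueError("attractor entries must be non-negative")
        if ((arr > 0).sum(axis=1) == 0).any():
            raise ValueError("all-zero attractor pattern")

    @property
    def cell_types(self) -> list[str]:
        return list(self.patterns.index)

    @property
    def genes(self) -> list[str]:
        return list(self.patterns.columns)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_genes(self) -> int:
        return self.patterns.shape[1]


def normalize_and_restrict(table: MarkerTable, dataset_genes) -> MarkerTable:
    """Restrict a raw marker table to ``dataset_genes`` and normalize it.

    Positive entries of each type are divided by that type's positive-marker
    count, negative by its negative-marker count; then each marker's
    positive entries are divided by the number of types in which it is
    positive and its negative entries by the number in which it is negative.
    Counts are taken after the restriction.  A type left with no positive
    marker is flagged unusable (all-zero column) with a warning.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    gene_set = set(dataset_genes)
    kept = [g for g in table.genes if g in gene_set]
    if not kept:
        raise ValueError("no marker genes present in the dataset")
    m = table.entries.loc[kept].to_numpy(dtype=float)

    pos = m > 0
    neg = m < 0
    pos_per_type = pos.sum(axis=0)          # markers per cell type
    neg_per_type = neg.sum(axis=0)
    unusable = pos_per_type == 0
    if unusable.any():
        bad = [t for t, u in zip(table.cell_types, unusable) if u]
        warnings.warn(
            f"cell types with no positive marker after restriction: {bad}"
        )

    out = m.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out[pos] = (m / np.where(pos_per_type == 0, 1, pos_per_type))[pos]
        out[neg] = (m / np.where(neg_per_type == 0, 1, neg_per_type))[neg]
        pos_per_marker = pos.sum(axis=1, keepdims=True)  # types per marker
        neg_per_marker = neg.sum(axis=1, keepdims=True)
        out[pos] = (out / np.where(pos_per_marker == 0, 1, pos_per_marker))[pos]
        out[neg] = (out / np.where(neg_per_marker == 0, 1, neg_per_marker))[neg]
    out[:, unusable] = 0.0

    return MarkerTable(
        pd.DataFrame(out, index=kept, columns=table.cell_types), normalized=True
    )


def build_attractors(normalized: MarkerTable) -> AttractorSet:
    """Zero the negative weights of a normalized table and store one
    pattern per cell type; types whose pattern is all-zero are excluded
    with a warning."""
    if not normalized.normalized:
        raise ValueError("build_attractors requires a normalized marker table")
    xi = normalized.entries.clip(lower=0.0).T  # types × genes
    empty = (xi.to_numpy() > 0).sum(axis=1) == 0
    if empty.any():
        bad = list(xi.index[empty])
        warnings.warn(f"cell types excluded from Hopfield classification: {bad}")
        xi = xi.loc[~empty]
    if xi.shape[0] == 0:
        raise ValueError("no usable attractor patterns")
    return AttractorSet(xi)
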