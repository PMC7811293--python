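"""Marker-voting cell-type annotation with a permutation null.

For each cluster c, the centroid Y_mc is the mean log-normalized expression
of marker m over the cluster's cells.  Per-marker z-scores across clusters,
Z_mc, are binarized at a threshold ζ (default 0.3): Z̃_mc = 1 when
Z_mc ≥ ζ.  Voting scores contract the normalized marker table against the
binarized centroids,

    V_kc = Σ_m M̃_km Z̃_mc ,

so positive markers that are significantly up in a cluster vote for type k
and detected negative markers vote against it.

Significance uses a permutation null: cells are reassigned to clusters at
random, preserving cluster sizes, and V recomputed for each of n_rand
replicates.  Λ_kc is the z-score of the observed V_kc in its null
distribution.  A second, distribution-free variant divides V_kc by the
maximum score type k could achieve (the sum of its positive normalized
weights).  In both variants the score is forced to zero when fewer than
10% of a type's known markers support the pair, and clusters whose best
score is not positive are labeled "Unassigned".  Several score matrices can
be merged into a consensus by a per-column rescaled geometric mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClusterLabels, ExpressionMatrix, MarkerTable

__all__ = [
    "CentroidMatrix",
    "AnnotationScores",
    "UNASSIGNED",
    "cluster_centroids",
    "binarize_zscores",
    "voting_scores",
    "null_significance",
    "fraction_scores",
    "assign_types",
    "consensus",
]

UNASSIGNED = "Unassigned"


@dataclass
class CentroidMatrix:
    """Marker × cluster centroid matrix with optional z-scores."""

    Y: pd.DataFrame
    Z: pd.DataFrame | None = None
    Zbin: pd.DataFrame | None = None
    zeta: float | None = None


@dataclass
class AnnotationScores:
    """Per (cell type, cluster) scores and the derived labels."""

    V: pd.DataFrame
    Lambda: pd.DataFrame
    labels: pd.Series                      # cluster -> type name
    method: str
    null_mean: pd.DataFrame | None = None
    null_sd: pd.DataFrame | None = None
    supporting: dict = field(default_factory=dict)     # (type, cluster) -> genes
    contradicting: dict = field(default_factory=dict)
    alternatives: dict = field(default_factory=dict)   # cluster -> [(type, Λ)]


def _group_matrix(labels: ClusterLabels, cells: list[str]) -> np.ndarray:
    """Cells × clusters column-mean operator (indicator / cluster size)."""
    lab = labels.reindex(cells)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])[:5]
        raise ValueError(f"cells without cluster label: {missing}")
    lab = lab.to_numpy(dtype=int)
    n_clusters = lab.max() + 1
    sizes = np.bincount(lab, minlength=n_clusters)
    if (sizes == 0).any():
        raise ValueError(f"empty clusters: {np.flatnonzero(sizes == 0).tolist()}")
    g = np.zeros((len(lab), n_clusters))
    g[np.arange(len(lab)), lab] = 1.0 / sizes[lab]
    return g


def cluster_centroids(
    matrix: ExpressionMatrix, labels: ClusterLabels, markers
) -> CentroidMatrix:
    """Mean expression of each marker over each cluster's cells."""
    present = [m for m in markers if m in matrix.values.index]
    absent = [m for m in markers if m not in matrix.values.index]
    if absent:
        warnings.warn(f"{len(absent)} marker genes absent from dataset, dropped")
    if not present:
        raise ValueError("no marker genes present in the dataset")
    g = _group_matrix(labels, matrix.cells)
    y = matrix.values.loc[present].to_numpy() @ g
    return CentroidMatrix(
        Y=pd.DataFrame(y, index=present, columns=range(g.shape[1]))
    )


def _zscore_rows(y: np.ndarray) -> np.ndarray:
    """Row-wise z-scores across clusters; constant rows get all zeros."""
    mean = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (y - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return z


def binarize_zscores(
    centroids: CentroidMatrix, zeta: float = 0.3, strict: bool = False
) -> CentroidMatrix:
    """Fill Z (per-marker z-scores across clusters) and its binarization.

    ``strict=True`` uses Z > ζ instead of the default Z ≥ ζ.
    """
    y = centroids.Y.to_numpy()
    if y.shape[1] < 2:
        raise ValueError("z-scores need at least 2 clusters")
    z = _zscore_rows(y)
    zbin = (z > zeta) if strict else (z >= zeta)
    return CentroidMatrix(
        Y=centroids.Y,
        Z=pd.DataFrame(z, index=centroids.Y.index, columns=centroids.Y.columns),
        Zbin=pd.DataFrame(
            zbin.astype(int), index=centroids.Y.index, columns=centroids.Y.columns
        ),
        zeta=zeta,
    )


def voting_scores(
    normalized: MarkerTable, zbin: pd.DataFrame, record_markers: bool = True
):
    """V = M̃ᵀ · Z̃ plus the supporting/contradicting marker bookkeeping.

    Returns ``(V, supporting, contradicting)`` where the latter two map
    (type, cluster) to the marker genes voting for/against the pair.
    """
    if not normalized.normalized:
        raise ValueError("voting_scores requires the normalized marker table")
    try:
        m = normalized.entries.loc[zbin.index].to_numpy()
    except KeyError as exc:
        raise ValueError(f"marker genes misaligned with centroid matrix: {exc}")
    zb = zbin.to_numpy()
    v = pd.DataFrame(m.T @ zb, index=normalized.cell_types, columns=zbin.columns)
    supporting: dict = {}
    contradicting: dict = {}
    if record_markers:
        genes = np.asarray(zbin.index)
        for ci, c in enumerate(zbin.columns):
            on = zb[:, ci] > 0
            for ki, k in enumerate(normalized.cell_types):
                supporting[(k, c)] = genes[on & (m[:, ki] > 0)].tolist()
                contradicting[(k, c)] = genes[on & (m[:, ki] < 0)].tolist()
    return v, supporting, contradicting


def _known_marker_counts(normalized: MarkerTable) -> np.ndarray:
    return (normalized.entries.to_numpy() != 0).sum(axis=0)


def _apply_low_support_rule(
    lam: np.ndarray,
    supporting_counts: np.ndarray,
    known_counts: np.ndarray,
    min_fraction: float = 0.1,
) -> np.ndarray:
    """Zero Λ_kc when supporting markers are below 10% of type k's known
    (positive plus negative) markers."""
    thin = supporting_counts < min_fraction * known_counts[:, None]
    out = lam.copy()
    out[thin] = 0.0
    return out


def null_significance(
    matrix: ExpressionMatrix,
    labels: ClusterLabels,
    normalized: MarkerTable,
    zeta: float = 0.3,
    n_rand: int = 10000,
    seed: int = 0,
    strict: bool = False,
    with_replacement: bool = False,
) -> AnnotationScores:
    """Annotate clusters by the z-score of V in a size-preserving null.

    Each replicate assigns cells to clusters at random (a label
    permutation by default, which preserves sizes exactly; sampling with
    replacement is available as an option) and recomputes Y, Z, Z̃ and V.
    Λ_kc = (V_kc − mean_null) / sd_null, zeroed by the low-support rule,
    and labels are the per-cluster argmax (``Unassigned`` when no type
    scores positive).
    """
    if n_rand < 100:
        warnings.warn(f"n_rand={n_rand} gives an unstable null distribution")
    centroids = binarize_zscores(
        cluster_centroids(matrix, labels, normalized.genes), zeta, strict
    )
    v, supporting, contradicting = voting_scores(normalized, centroids.Zbin)
    xm = matrix.values.loc[centroids.Y.index].to_numpy()
    g = _group_matrix(labels, matrix.cells)
    n_cells = xm.shape[1]

    rng = np.random.default_rng(seed)
    mdat = normalized.entries.loc[centroids.Y.index].to_numpy()
    acc = np.zeros_like(v.to_numpy())
    acc2 = np.zeros_like(acc)
    for _ in range(n_rand):
        if with_replacement:
            idx = rng.integers(0, n_cells, size=n_cells)
        else:
            idx = rng.permutation(n_cells)
        yr = xm[:, idx] @ g
        zr = _zscore_rows(yr)
        zbr = (zr > zeta) if strict else (zr >= zeta)
        vr = mdat.T @ zbr
        acc += vr
        acc2 += vr * vr
    null_mean = acc / n_rand
    null_var = np.maximum(acc2 / n_rand - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var)

    with np.errstate(invalid="ignore", divide="ignore"):
        lam = (v.to_numpy() - null_mean) / null_sd
    degenerate = null_sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} (type, cluster) pairs with zero null "
            "spread; their scores are set to 0"
        )
        lam[degenerate] = 0.0

    sup_counts = np.array(
        [
            [len(supporting[(k, c)]) for c in centroids.Zbin.columns]
            for k in normalized.cell_types
        ]
    )
    lam = _apply_low_support_rule(lam, sup_counts, _known_marker_counts(normalized))
    lam_df = pd.DataFrame(lam, index=v.index, columns=v.columns)
    labels_out, alternatives = assign_types(lam_df)
    return AnnotationScores(
        V=v,
        Lambda=lam_df,
        labels=labels_out,
        method="voting",
        null_mean=pd.DataFrame(null_mean, index=v.index, columns=v.columns),
        null_sd=pd.DataFrame(null_sd, index=v.index, columns=v.columns),
        supporting=supporting,
        contradicting=contradicting,
        alternatives=alternatives,
    )


def fraction_scores(
    v: pd.DataFrame,
    normalized: MarkerTable,
    supporting: dict | None = None,
) -> pd.DataFrame:
    """Score variant Λ_kc = V_kc / Σ_{m: M_km>0} M̃_km.

    The denominator is the best score type k could reach if all its
    positive markers were supported and no negative marker detected, so
    Λ ≤ 1 with equality exactly at full support.  Types with no positive
    weight get a zero row; the 10% low-support rule applies when the
    supporting-marker bookkeeping is supplied.
    """
    m = normalized.entries.to_numpy()
    denom = np.where(m > 0, m, 0.0).sum(axis=0)
    lam = v.to_numpy().astype(float).copy()
    usable = denom > 0
    lam[usable] = lam[usable] / denom[usable, None]
    lam[~usable] = 0.0
    if supporting is not None:
        sup_counts = np.array(
            [[len(supporting[(k, c)]) for c in v.columns] for k in v.index]
        )
        lam = _apply_low_support_rule(
            lam, sup_counts, _known_marker_counts(normalized)
        )
    return pd.DataFrame(lam, index=v.index, columns=v.columns)


def assign_types(lam: pd.DataFrame):
    """Per-cluster argmax labels plus ranked alternatives.

    A cluster whose scores are all ≤ 0 is labeled ``Unassigned``.  Exact
    ties go to the lexicographically first type name and are logged.
    """
    if lam.size == 0:
        raise ValueError("empty score matrix")
    if not np.all(np.isfinite(lam.to_numpy())):
        raise ValueError("non-finite scores")
    labels = {}
    alternatives = {}
    order_names = np.argsort(lam.index)  # lexicographic tie-break
    for c in lam.columns:
        col = lam[c]
        ranked = sorted(
            col.items(), key=lambda kv: (-kv[1], kv[0])
        )
        alternatives[c] = ranked
        best_type, best_val = ranked[0]
        if best_val <= 0:
            labels[c] = UNASSIGNED
        else:
            labels[c] = best_type
            if sum(1 for _, val in ranked if val == best_val) > 1:
                warnings.warn(f"cluster {c}: tie at score {best_val}, "
                              f"choosing {best_type!r} lexicographically")
    del order_names
    return pd.Series(labels), alternatives


def consensus(score_matrices: list[pd.DataFrame]):
    """Combine score matrices by a rescaled geometric mean.

    Each matrix is clipped at zero and every cluster column rescaled to
    maximum 1 (all-zero columns stay zero); the consensus is the
    elementwise geometric mean, so a type scored zero by any method stays
    zero.  Returns ``(consensus Λ, labels, alternatives)``.
    """
    if not score_matrices:
        raise ValueError("no score matrices")
    shape = score_matrices[0].shape
    index = score_matrices[0].index
    columns = score_matrices[0].columns
    prod = np.ones(shape)
    for sm in score_matrices:
        if sm.shape != shape or not sm.index.equals(index):
            raise ValueError("score matrices must share type × cluster shape")
        arr = sm.to_numpy(dtype=float).clip(min=0.0)
        colmax = arr.max(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            arr = np.where(colmax > 0, arr / colmax, 0.0)
        prod *= arr
    cons = pd.DataFrame(prod ** (1.0 / len(score_matrices)), index=index,
                        columns=columns)
    labels, alternatives = assign_types(cons)
    return cons, labels, alternatives
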