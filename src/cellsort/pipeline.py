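"""High-level annotation pipeline: one call from counts to cluster labels.

Thin orchestration over the library modules; every tunable is forwarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import hopfield as hf
from .io import ClusterLabels, ExpressionMatrix, GeneNetwork, MarkerTable
from .markers import build_attractors, normalize_and_restrict
from .voting import (
    AnnotationScores,
    assign_types,
    binarize_zscores,
    cluster_centroids,
    consensus,
    fraction_scores,
    null_significance,
    voting_scores,
)

__all__ = ["AnnotationResult", "annotate"]


@dataclass
class AnnotationResult:
    method: str
    cluster_labels: pd.Series          # cluster -> type
    cell_labels: pd.Series             # cell -> type
    scores: pd.DataFrame               # types × clusters score matrix
    details: dict


def _cells_from_clusters(cluster_labels: pd.Series,
                         labels: ClusterLabels) -> pd.Series:
    return labels.map(cluster_labels).rename("cell_type")


def annotate(
    matrix: ExpressionMatrix,
    labels: ClusterLabels,
    table: MarkerTable,
    method: str = "voting",
    zeta: float = 0.3,
    n_rand: int = 10000,
    network: GeneNetwork | None = None,
    temperature: float = 0.2,
    reps: int = 10,
    steps: int = 200,
    seed: int = 0,
) -> AnnotationResult:
    """Annotate clusters of a log-normalized matrix with one of the methods.

    ``method`` is one of ``voting`` (permutation-null voting), ``fraction``
    (max-score-normalized voting), ``hopfield`` (attractor classifier;
    complete-graph couplings when ``network`` is None) or ``consensus``
    (geometric mean of the voting and hopfield score matrices).
    """
    if not matrix.is_lognormalized:
        raise ValueError("annotate expects a log-normalized matrix")
    normalized = normalize_and_restrict(table, matrix.genes)

    def run_voting() -> AnnotationScores:
        return null_significance(
            matrix, labels, normalized, zeta=zeta, n_rand=n_rand, seed=seed
        )

    def run_hopfield():
        attractors = build_attractors(normalized)
        model = hf.build_model(attractors, network=network,
                               temperature=temperature)
        centroids = binarize_zscores(
            cluster_centroids(matrix, labels, attractors.genes), zeta
        )
        return hf.score_matrix(centroids, model, reps=reps, steps=steps,
                               seed=seed, zeta=zeta)

    if method == "voting":
        scores = run_voting()
        cl, sm, details = scores.labels, scores.Lambda, {"scores": scores}
    elif method == "fraction":
        centroids = binarize_zscores(
            cluster_centroids(matrix, labels, normalized.genes), zeta
        )
        v, supporting, contradicting = voting_scores(normalized, centroids.Zbin)
        lam = fraction_scores(v, normalized, supporting)
        cl, alternatives = assign_types(lam)
        sm = lam
        details = {"V": v, "supporting": supporting,
                   "contradicting": contradicting,
                   "alternatives": alternatives}
    elif method == "hopfield":
        sm, cl = run_hopfield()
        details = {}
    elif method == "consensus":
        voting_scores_res = run_voting()
        hop_scores, hop_labels = run_hopfield()
        hop_aligned = hop_scores.reindex(voting_scores_res.Lambda.index).fillna(0.0)
        sm, cl, alternatives = consensus([voting_scores_res.Lambda, hop_aligned])
        details = {"voting": voting_scores_res, "hopfield_scores": hop_scores,
                   "hopfield_labels": hop_labels, "alternatives": alternatives}
    else:
        raise ValueError(f"unknown method {method!r}")

    return AnnotationResult(
        method=method,
        cluster_labels=cl,
        cell_labels=_cells_from_clusters(cl, labels),
        scores=sm,
        details=details,
    )
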