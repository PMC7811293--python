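"""Benchmark experiment harnesses on synthetic data.

Two designs are reproduced at desk scale:

* annotation of random mixtures of planted cell types, scored by
  support-weighted F1 over assigned cells and the unassigned fraction, for
  the permutation-null voting annotator, the Hopfield classifier
  (complete-graph couplings) and their consensus;
* anomaly detection of a small number of phenotypically shifted cells
  spiked into a typical background, scored by the rank-threshold ROC
  averaged over seeded repeats, with a same-phenotype negative control.

All randomness derives from one root seed via named child seeds, so each
stage is independently reproducible.
"""

from __future__ import annotations

import numpy as np

from .evaluate import evaluate_annotation, evaluate_anomaly
from .hopfield import build_model, score_matrix
from .io import ClusterLabels
from .markers import build_attractors, normalize_and_restrict
from .qc import normalize
from .synthetic import (DEFAULT_ANOMALY_SHIFT, synth_anomaly_mixture,
                        synth_expression, synth_marker_table)
from .voting import binarize_zscores, cluster_centroids, consensus, \
    null_significance

__all__ = ["annotation_mixture_experiment", "anomaly_detection_experiment"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _random_mixture_sizes(rng, n_types: int, total: int,
                          min_cells: int = 40) -> list[int]:
    """Random per-type fractions with a floor so every cluster is usable."""
    fracs = rng.dirichlet(np.ones(n_types))
    sizes = np.maximum((fracs * total).astype(int), min_cells)
    return sizes.tolist()


def annotation_mixture_experiment(
    n_mixtures: int = 20,
    n_types: int = 8,
    cells_per_mixture: int = 2000,
    markers_per_type: int = 5,
    n_shared: int = 4,
    n_negative: int = 8,
    effect: float = 5.0,
    n_rand: int = 1000,
    zeta: float = 0.3,
    seed: int = 0,
) -> dict:
    """Annotate random planted-type mixtures with all three methods.

    Each mixture draws the planted types in random fractions; clusters are
    the pure-type groups, mirroring a gold standard of sorted populations.
    Returns per-method F1 and unassigned-fraction lists plus their means.
    """
    seeds = _child_seeds(seed, 3)
    table = synth_marker_table(n_types, markers_per_type, n_shared,
                               n_negative, seed=int(seeds[0]))
    rng = np.random.default_rng(int(seeds[1]))
    mixture_seeds = _child_seeds(int(seeds[2]), n_mixtures)

    results: dict = {m: {"f1": [], "unassigned": []}
                     for m in ("voting", "hopfield", "consensus")}
    for i in range(n_mixtures):
        sizes = _random_mixture_sizes(rng, n_types, cells_per_mixture)
        matrix, truth = synth_expression(
            table, sizes, n_background_genes=100, effect=effect,
            seed=int(mixture_seeds[i]),
        )
        lognorm = normalize(matrix)
        type_index = {t: k for k, t in enumerate(table.cell_types)}
        labels = ClusterLabels.from_mapping(
            {c: type_index[t] for c, t in truth.cell_types.items()}
        )
        normalized = normalize_and_restrict(table, lognorm.genes)

        voting = null_significance(lognorm, labels, normalized, zeta=zeta,
                                 n_rand=n_rand, seed=int(mixture_seeds[i]))
        attractors = build_attractors(normalized)
        model = build_model(attractors)
        centroids = binarize_zscores(
            cluster_centroids(lognorm, labels, attractors.genes), zeta)
        hop_scores, hop_labels = score_matrix(
            centroids, model, seed=int(mixture_seeds[i]), zeta=zeta)
        hop_aligned = hop_scores.reindex(voting.Lambda.index).fillna(0.0)
        _, cons_labels, _ = consensus([voting.Lambda, hop_aligned])

        for method, cluster_labels in (("voting", voting.labels),
                                       ("hopfield", hop_labels),
                                       ("consensus", cons_labels)):
            predicted = labels.map(cluster_labels)
            f1, unassigned = evaluate_annotation(predicted, truth.cell_types)
            results[method]["f1"].append(f1)
            results[method]["unassigned"].append(unassigned)

    for method in results:
        f1s = [f for f in results[method]["f1"] if f is not None]
        results[method]["mean_f1"] = float(np.mean(f1s)) if f1s else None
        results[method]["mean_unassigned"] = float(
            np.mean(results[method]["unassigned"]))
    return results


def anomaly_detection_experiment(
    n_repeats: int = 20,
    n_base: int = 1600,
    n_anomalous: int = 20,
    shift: float = DEFAULT_ANOMALY_SHIFT,
    mode: str = "shifted",
    n_trees: int = 100,
    psi: int = 256,
    seed: int = 0,
) -> dict:
    """Spike-in detection by anomaly rank, averaged over seeded repeats.

    A fixed 2-type background of ``n_base`` cells receives ``n_anomalous``
    spike-ins per repeat (freshly drawn each time); each repeat normalizes
    the mixture, fits a forest and scores every cell.  Returns the AUC of
    the repeat-averaged rank-threshold ROC and the per-repeat AUCs.
    """
    from .anomaly import fit_forest, score_cells

    seeds = _child_seeds(seed, 2 + n_repeats)
    table = synth_marker_table(2, markers_per_type=5, seed=int(seeds[0]))
    base, _ = synth_expression(
        table, [n_base // 2, n_base - n_base // 2],
        n_background_genes=300, effect=5.0, seed=int(seeds[1]),
    )
    realizations = []
    per_repeat = []
    for i in range(n_repeats):
        rep_seed = int(seeds[2 + i])
        mixture, truth = synth_anomaly_mixture(
            base, n_anomalous=n_anomalous, shift=shift, mode=mode,
            seed=rep_seed,
        )
        lognorm = normalize(mixture)
        model = fit_forest(lognorm, n_trees=n_trees, psi=psi, seed=rep_seed)
        scores = score_cells(model, lognorm)
        pair = (scores["score"].to_numpy(), truth.anomaly.to_numpy())
        realizations.append(pair)
        auc_i, _, _ = evaluate_anomaly([pair])
        per_repeat.append(auc_i)
    auc, fpr, tpr = evaluate_anomaly(realizations)
    return {
        "mean_auc": auc,
        "per_repeat_auc": per_repeat,
        "fpr": fpr,
        "mean_tpr": tpr,
    }
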