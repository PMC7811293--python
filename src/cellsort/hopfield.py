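"""Hopfield associative-memory classifier over a gene network.

Cell types are stored as attractor patterns ξ̃ (non-negative columns of the
normalized marker table).  The coupling between genes i and j is the
projection-rule form restricted to the interaction network,

    J_ij = (A_ij / N) Σ_{μν} ξ̃_i^μ (Q⁻¹)_{μν} ξ̃_j^ν ,
    Q_{μν} = (1/N) Σ_i ξ̃_i^μ ξ̃_i^ν ,

where A is the adjacency of the gene–gene network (complete graph when no
network is supplied) and Q⁻¹ corrects for correlation between the stored
patterns.  Spins σ_i ∈ {−1, 0, +1} start from the cluster's binarized
centroid z-scores and evolve by a stochastic asynchronous dynamics: at
step t each node is selected with probability ramping linearly from 0.025
to 0.5 over the first 100 steps, and a selected node draws +1 with
probability (1 + exp(−2 h_i / T))⁻¹ on the local field
h_i = Σ_j J_ij σ_j + h_i^ext.  A node switching from +1 to −1 is set to 0
instead (and a 0 node never drops to −1), which dilutes the network over
time and stabilizes convergence.  Classification takes the attractor with
the largest non-negative overlap

    m^μ = (1/N) Σ_{i,ν} σ_i ξ̃_i^ν (Q⁻¹)_{νμ}

at the final step; repeated stochastic runs vote, and their label
frequencies form the cluster's score column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import GeneNetwork
from .markers import AttractorSet
from .voting import UNASSIGNED, CentroidMatrix

__all__ = [
    "HopfieldModel",
    "PatternSet",
    "SpinState",
    "OverlapTrajectory",
    "build_model",
    "init_state",
    "evolve",
    "overlaps",
    "classify_cluster",
    "UPDATE_PROB_START",
    "UPDATE_PROB_END",
    "UPDATE_RAMP_STEPS",
]

# asynchronous schedule: node-update probability ramps linearly over the
# first UPDATE_RAMP_STEPS steps, then stays at UPDATE_PROB_END
UPDATE_PROB_START = 0.025
UPDATE_PROB_END = 0.5
UPDATE_RAMP_STEPS = 100


@dataclass
class PatternSet:
    """Arbitrary stored patterns (p × N DataFrame), e.g. classical ±1
    memories; :class:`cellsort.markers.AttractorSet` adds the marker-derived
    non-negativity constraint."""

    patterns: pd.DataFrame

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


def _coerce_patterns(obj) -> "PatternSet | AttractorSet":
    if hasattr(obj, "patterns"):
        return obj
    arr = np.atleast_2d(np.asarray(obj, dtype=float))
    return PatternSet(
        pd.DataFrame(
            arr,
            index=[f"P{i}" for i in range(arr.shape[0])],
            columns=[f"n{i}" for i in range(arr.shape[1])],
        )
    )


@dataclass
class HopfieldModel:
    attractors: "AttractorSet | PatternSet"
    Q: np.ndarray              # p × p pattern correlation
    Qinv: np.ndarray
    A: np.ndarray              # N × N adjacency, zero diagonal
    J: np.ndarray              # N × N coupling
    temperature: float = 0.2
    h_ext: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.attractors.n_genes

    @property
    def genes(self) -> list[str]:
        return self.attractors.genes


@dataclass
class SpinState:
    sigma: np.ndarray          # N-vector over {-1, 0, +1}
    t: int = 0

    def __post_init__(self) -> None:
        if not np.isin(self.sigma, (-1, 0, 1)).all():
            raise ValueError("spins must be in {-1, 0, +1}")


@dataclass
class OverlapTrajectory:
    m: np.ndarray              # steps × p overlaps
    cell_types: list[str]
    final_label: str | None = None
    frequencies: dict = field(default_factory=dict)


def update_probability(t: int) -> float:
    """Per-node selection probability at step t."""
    frac = min(t, UPDATE_RAMP_STEPS) / UPDATE_RAMP_STEPS
    return UPDATE_PROB_START + (UPDATE_PROB_END - UPDATE_PROB_START) * frac


def build_model(
    attractors,
    network: GeneNetwork | None = None,
    temperature: float = 0.2,
    h_ext: np.ndarray | None = None,
    use_q: bool = True,
) -> HopfieldModel:
    """Assemble couplings from stored patterns and the gene network.

    ``attractors`` is an :class:`~cellsort.markers.AttractorSet` (or any
    p × N pattern array, e.g. classical ±1 memories).  ``network=None``
    uses the complete graph (A_ij = 1 − δ_ij).  Q is inverted by
    pseudo-inverse with a relative singular-value cutoff of 1e-10 when
    singular, with a warning.  ``use_q=False`` replaces Q⁻¹ by the
    identity (plain Hebbian storage), the construction used for the
    quasi-energy landscapes.
    """
    attractors = _coerce_patterns(attractors)
    xi = attractors.patterns.to_numpy()  # p × N
    p, n = xi.shape
    if n < 2:
        raise ValueError("need at least 2 genes")
    if ((xi != 0).sum(axis=1) == 0).any():
        raise ValueError("all-zero attractor pattern")
    q = xi @ xi.T / n
    if use_q:
        cond_bad = np.linalg.matrix_rank(q) < p
        if cond_bad:
            warnings.warn("pattern correlation matrix singular; using pseudo-inverse")
            qinv = np.linalg.pinv(q, rcond=1e-10)
        else:
            qinv = np.linalg.inv(q)
    else:
        qinv = np.eye(p)
    if network is None:
        a = np.ones((n, n))
        np.fill_diagonal(a, 0.0)
    else:
        a = network.adjacency(attractors.genes)
    j = (a / n) * (xi.T @ qinv @ xi)
    if h_ext is None:
        h_ext = np.zeros(n)
    return HopfieldModel(
        attractors=attractors, Q=q, Qinv=qinv, A=a, J=j,
        temperature=temperature, h_ext=np.asarray(h_ext, dtype=float),
    )


def init_state(
    centroids: CentroidMatrix, cluster, model: HopfieldModel, zeta: float = 0.3
) -> SpinState:
    """σ_i = +1 where the cluster's centroid z-score is ≥ ζ, else −1."""
    if centroids.Z is None:
        raise ValueError("centroid z-scores not computed")
    missing = [g for g in model.genes if g not in centroids.Z.index]
    if missing:
        raise ValueError(f"genes missing from centroid matrix: {missing[:5]}")
    z = centroids.Z.loc[model.genes, cluster].to_numpy()
    sigma = np.where(z >= zeta, 1, -1).astype(np.int8)
    return SpinState(sigma=sigma, t=0)


def overlaps(state: SpinState, model: HopfieldModel) -> np.ndarray:
    """Correlation-corrected overlap of the state with each attractor."""
    xi = model.attractors.patterns.to_numpy()
    n = model.n_nodes
    if state.sigma.shape[0] != n:
        raise ValueError("state not aligned to model nodes")
    return (state.sigma @ xi.T / n) @ model.Qinv


def evolve(
    state: SpinState,
    model: HopfieldModel,
    steps: int = 200,
    seed: int = 0,
    record: bool = True,
):
    """Run the stochastic dynamics; returns (trajectory, final state).

    At T ≤ 0 the deterministic limit applies: a selected node takes
    sign(h), with a fair coin at h = 0.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = state.sigma.astype(np.int8).copy()
    n = sigma.shape[0]
    temp = model.temperature
    traj = np.empty((steps, model.attractors.n_patterns)) if record else None
    for step in range(steps):
        selected = rng.random(n) < update_probability(state.t + step)
        if selected.any():
            h = model.J @ sigma + model.h_ext
            if temp > 0:
                p_up = expit(2.0 * h / temp)
            else:
                p_up = np.where(h > 0, 1.0, np.where(h < 0, 0.0, 0.5))
            draw_up = rng.random(n) < p_up
            new = sigma.copy()
            sel_up = selected & draw_up
            sel_down = selected & ~draw_up
            new[sel_up] = 1
            # +1 drawing -1 is parked at 0; 0 drawing -1 stays 0
            new[sel_down & (sigma == 1)] = 0
            new[sel_down & (sigma == -1)] = -1
            sigma = new
        if record:
            traj[step] = overlaps(SpinState(sigma, 0), model)
    final = SpinState(sigma=sigma, t=state.t + steps)
    trajectory = OverlapTrajectory(
        m=traj if record else np.empty((0, model.attractors.n_patterns)),
        cell_types=model.attractors.cell_types,
    )
    return trajectory, final


def _label_from_overlaps(m_final: np.ndarray, cell_types: list[str]) -> str:
    nonneg = m_final >= 0
    if not nonneg.any():
        return UNASSIGNED
    best = np.flatnonzero(nonneg)[np.argmax(m_final[nonneg])]
    return cell_types[best]


def classify_cluster(
    centroids: CentroidMatrix,
    cluster,
    model: HopfieldModel,
    reps: int = 10,
    steps: int = 200,
    seed: int = 0,
    zeta: float = 0.3,
):
    """Label one cluster by repeated stochastic runs.

    Each repetition initializes from the cluster's centroid z-scores,
    evolves, and votes for the attractor with the largest non-negative
    final overlap (or ``Unassigned``).  Returns ``(modal label,
    frequencies over labels, trajectories)``; frequencies sum to 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    counts: dict[str, int] = {}
    trajectories = []
    for r in range(reps):
        state = init_state(centroids, cluster, model, zeta)
        traj, final = evolve(state, model, steps=steps, seed=int(seeds[r]))
        label = _label_from_overlaps(overlaps(final, model), model.attractors.cell_types)
        traj.final_label = label
        trajectories.append(traj)
        counts[label] = counts.get(label, 0) + 1
    freqs = {k: v / reps for k, v in counts.items()}
    # modal pick: highest frequency, ties to lexicographically first real
    # type, Unassigned last
    ranked = sorted(
        freqs.items(), key=lambda kv: (-kv[1], kv[0] == UNASSIGNED, kv[0])
    )
    modal_label = ranked[0][0]
    return modal_label, freqs, trajectories


def score_matrix(
    centroids: CentroidMatrix,
    model: HopfieldModel,
    reps: int = 10,
    steps: int = 200,
    seed: int = 0,
    zeta: float = 0.3,
):
    """Classify every cluster; returns (frequency score matrix, labels).

    The score matrix rows are cell types (``Unassigned`` excluded),
    columns clusters; entries are label frequencies over repetitions.
    """
    clusters = list(centroids.Y.columns)
    types = model.attractors.cell_types
    scores = pd.DataFrame(0.0, index=types, columns=clusters)
    labels = {}
    child = np.random.SeedSequence(seed).generate_state(len(clusters)) % (2**31)
    for ci, c in enumerate(clusters):
        modal, freqs, _ = classify_cluster(
            centroids, c, model, reps=reps, steps=steps, seed=int(child[ci]),
            zeta=zeta,
        )
        labels[c] = modal
        for k, f in freqs.items():
            if k != UNASSIGNED:
                scores.loc[k, c] = f
    return scores, pd.Series(labels)
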