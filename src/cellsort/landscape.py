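"""Quasi-energy landscape sampling around the stored attractors.

The coupling matrix defines a Lyapunov-like quasi-energy

    E(σ) = −(1/2) Σ_{ij} σ_i J_ij σ_j ,

whose minima sit at the stored cell-type patterns.  The landscape is made
visible by perturbing each attractor's ±1 encoding with sign flips at a
range of rates, evaluating E for every perturbed state, and projecting all
states onto the first two principal components of the attractor states
themselves.  The module emits the (x, y, E, attractor) table; rendering is
left to any plotting layer.

By default the landscape coupling keeps the gene-network adjacency A but
omits the pattern-correlation correction Q (plain Hebbian storage); both
toggles are exposed through :func:`cellsort.hopfield.build_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hopfield import HopfieldModel, SpinState

__all__ = ["LandscapeSample", "energy", "sample_basins", "project_landscape"]

DEFAULT_FLIP_RATES = (0.05, 0.1, 0.2, 0.3)


@dataclass
class LandscapeSample:
    states: np.ndarray           # n_samples × N spins
    energies: np.ndarray         # n_samples
    attractor_index: np.ndarray  # source attractor per sample
    flip_rate: np.ndarray        # noise level per sample
    cell_types: list[str]
    coords2d: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.coords2d is None:
            raise ValueError("run project_landscape first")
        return pd.DataFrame(
            {
                "x": self.coords2d[:, 0],
                "y": self.coords2d[:, 1],
                "energy": self.energies,
                "attractor": [self.cell_types[i] for i in self.attractor_index],
                "flip_rate": self.flip_rate,
            }
        )


def energy(state: SpinState | np.ndarray, model: HopfieldModel) -> float:
    """E = −(1/2) σᵀ J σ."""
    sigma = state.sigma if isinstance(state, SpinState) else np.asarray(state)
    if sigma.shape[-1] != model.n_nodes:
        raise ValueError("state not aligned to model nodes")
    return float(-0.5 * sigma @ model.J @ sigma)


def _binarize_attractors(model: HopfieldModel) -> np.ndarray:
    """Attractor spin encoding for sampling: entry > 0 → +1, else −1."""
    xi = model.attractors.patterns.to_numpy()
    return np.where(xi > 0, 1, -1).astype(np.int8)


def sample_basins(
    model: HopfieldModel,
    n_per_attractor: int = 1000,
    flip_rates=DEFAULT_FLIP_RATES,
    seed: int = 0,
) -> LandscapeSample:
    """Perturb each attractor with sign flips and record quasi-energies.

    For every attractor and flip rate r, ``n_per_attractor`` states are
    drawn by independently flipping each spin with probability r.  The
    unperturbed attractor states are included (flip rate 0).
    """
    rng = np.random.default_rng(seed)
    base = _binarize_attractors(model)
    p, n = base.shape
    states = [base]
    attractor_index = [np.arange(p)]
    rates = [np.zeros(p)]
    for r in flip_rates:
        for mu in range(p):
            flips = rng.random((n_per_attractor, n)) < r
            states.append(np.where(flips, -base[mu], base[mu]))
            attractor_index.append(np.full(n_per_attractor, mu))
            rates.append(np.full(n_per_attractor, r))
    all_states = np.vstack(states)
    energies = -0.5 * np.einsum("si,ij,sj->s", all_states, model.J, all_states)
    return LandscapeSample(
        states=all_states,
        energies=energies,
        attractor_index=np.concatenate(attractor_index),
        flip_rate=np.concatenate(rates),
        cell_types=model.attractors.cell_types,
    )


def project_landscape(
    sample: LandscapeSample, model: HopfieldModel
) -> LandscapeSample:
    """Project sampled states onto the attractors' first two principal axes.

    The axes are computed from the binarized attractor states only, so the
    attractor coordinates do not depend on how many noise samples were
    drawn; all sampled states are then projected onto the same two axes.
    """
    base = _binarize_attractors(model).astype(float)
    if base.shape[0] < 2:
        raise ValueError("need at least 2 attractors for a 2D projection")
    center = base.mean(axis=0)
    _, _, vt = np.linalg.svd(base - center, full_matrices=False)
    axes = vt[:2]  # 2 × N
    sample.coords2d = (sample.states - center) @ axes.T
    return sample
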