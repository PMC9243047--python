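"""Boltzmann populations and cumulative-contribution conformer selection.

An optimized conformer ensemble is reduced to the minimal set of conformers
that together contribute at least a threshold fraction (default 50%) of the
classical partition function Z. Weights are computed from the energies of
whichever stage produced the ensemble; the caller records which energy
column fed the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL_PER_MOL_K
from .errors import EmptyEnsembleError

__all__ = ["EnsembleSelection", "boltzmann_weights", "select_cumulative", "select_ensemble"]

DEFAULT_SELECTION_TEMPERATURE = 298.15  # K


@dataclass(frozen=True)
class EnsembleSelection:
    """Result of the ≥threshold-of-Z truncation of a conformer ensemble."""

    n_total: int
    weights: np.ndarray  # normalized, original conformer order
    z_value: float  # Σ exp(−(Eᵢ−Emin)/kBT), minimum-shifted
    selected_indices: tuple[int, ...]  # original indices, by descending weight
    threshold: float

    @property
    def n_selected(self) -> int:
        """n′ — the number of conformers kept."""
        return len(self.selected_indices)

    @property
    def selected_fraction(self) -> float:
        return float(np.sum(self.weights[list(self.selected_indices)]))

    @property
    def percent_of_z(self) -> float:
        return 100.0 * self.selected_fraction


def boltzmann_weights(energies, temperature: float = DEFAULT_SELECTION_TEMPERATURE) -> np.ndarray:
    """Normalized Boltzmann weights wᵢ = exp(−(Eᵢ−Emin)/kBT)/Σ.

    Energies in kcal/mol. Minimum-shifted for numerical stability; invariant
    under adding a constant to all energies. Σw = 1 to within 1e-12.
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise EmptyEnsembleError("cannot weight an empty ensemble")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energy in ensemble")
    shifted = e - e.min()
    boltz = np.exp(-shifted / (KB_KCAL_PER_MOL_K * temperature))
    return boltz / boltz.sum()


def select_cumulative(weights, threshold: float = 0.5) -> EnsembleSelection:
    """Keep the minimal set of conformers whose cumulative weight ≥ *threshold*.

    Conformers are ranked by weight descending (ties broken by original
    index ascending) and the shortest qualifying prefix of that ranking is
    selected; the remainder — the minor contributors — is discarded.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise EmptyEnsembleError("cannot select from an empty ensemble")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if np.any(w < 0):
        raise ValueError("negative weight")
    total = w.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {total})")
    # stable sort on (-weight, index): ties resolved by original index ascending
    order = np.lexsort((np.arange(w.size), -w))
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, threshold - 1e-12)) + 1
    k = min(k, w.size)
    return EnsembleSelection(
        n_total=int(w.size),
        weights=w,
        z_value=float(total),
        selected_indices=tuple(int(i) for i in order[:k]),
        threshold=threshold,
    )


def select_ensemble(
    energies,
    temperature: float = DEFAULT_SELECTION_TEMPERATURE,
    threshold: float = 0.5,
) -> EnsembleSelection:
    """Weights + cumulative selection in one call, with the true Z recorded."""
    e = np.asarray(list(energies), dtype=float)
    w = boltzmann_weights(e, temperature)
    sel = select_cumulative(w, threshold)
    z = float(np.sum(np.exp(-(e - e.min()) / (KB_KCAL_PER_MOL_K * temperature))))
    return EnsembleSelection(
        n_total=sel.n_total,
        weights=sel.weights,
        z_value=z,
        selected_indices=sel.selected_indices,
        threshold=threshold,
    )
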