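"""Ligand solvation-shell counting and weighted 2D free-energy landscapes.

The landscape bins a per-frame binding coordinate (computed externally,
e.g. a tICA projection) against the number of waters within 5 Å of the
ligand, and reports ΔG(bin) = −k_B T ln(P(bin)/P_max) with empty bins
masked. Without frame weights the histogram uses raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import KB_KCAL, FrameSeries, Topology, minimum_image_displacement
from .core import AtomRole

SHELL_DISTANCE = 5.0  # Å, roughly the first two solvation shells


@dataclass
class FESGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray  # kcal/mol, masked where empty
    temperature: float

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature


def count_shell_waters(
    frames: FrameSeries,
    topology: Topology,
    ligand_atom_indices: Sequence[int],
    shell: float = SHELL_DISTANCE,
) -> np.ndarray:
    """Per-frame count of waters whose oxygen is within the ligand shell."""
    ligand_atom_indices = np.asarray(ligand_atom_indices, dtype=int)
    if len(ligand_atom_indices) == 0:
        raise ValueError("no ligand atoms given")
    heavy = np.array(
        [i for i in ligand_atom_indices if topology.atoms[i].element != "H"]
    )
    if len(heavy) == 0:
        raise ValueError("ligand atom set has no heavy atoms")
    oxygen_idx = np.array([mol[0] for mol in topology.water_molecules])
    counts = np.zeros(frames.n_frames, dtype=int)
    if len(oxygen_idx) == 0:
        return counts
    for f in range(frames.n_frames):
        coords = frames.coordinates[f]
        box = frames.box_lengths[f]
        delta = coords[oxygen_idx][:, None, :] - coords[heavy][None, :, :]
        delta = minimum_image_displacement(delta, box)
        d = np.sqrt((delta**2).sum(axis=2)).min(axis=1)
        counts[f] = int((d <= shell).sum())
    return counts


def free_energy_landscape(
    x: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray] = None,
    bins: Optional[tuple] = None,
    temperature: float = 300.0,
) -> FESGrid:
    """Weighted 2D free-energy surface over (binding coordinate, shell count).

    ΔG(bin) = −k_B T ln(P/P_max); the most probable bin is 0 and empty
    bins are masked. y is binned at integer values by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != x.shape:
            raise ValueError("weights must match x and y")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    if bins is None:
        ylo, yhi = int(np.floor(y.min())), int(np.ceil(y.max()))
        y_edges = np.arange(ylo - 0.5, yhi + 1.5)
        bins = (60, y_edges)
    hist, x_edges, y_edges = np.histogram2d(x, y, bins=bins, weights=weights)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    prob = hist / total
    pmax = prob.max()
    masked = np.ma.masked_where(prob <= 0, prob)
    kT = KB_KCAL * temperature
    free_energy = -kT * np.ma.log(masked / pmax)
    if (prob > 0).sum() == 1:
        import warnings

        warnings.warn("all frames fall in a single bin", stacklevel=2)
    return FESGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        free_energy=free_energy,
        temperature=temperature,
    )
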