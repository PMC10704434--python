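"""Core domain types shared across the hydration-site analysis pipeline.

Conventions used throughout the package:

* lengths in Å, energies in kcal/mol, charges in elementary charge units;
* orthorhombic periodic boxes with the minimum-image convention;
* 0-based atom, molecule and frame indices everywhere in memory
  (1-based serials appear only in PDB output);
* water–water interaction energies carry the ½ pair-sharing convention so
  that the bulk per-water total matches the conventional TIP3P value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636
# Boltzmann constant in kcal/(mol·K)
KB_KCAL = 0.0019872041


class AtomRole(str, enum.Enum):
    SOLUTE = "solute"
    WATER_OXYGEN = "water_oxygen"
    WATER_HYDROGEN = "water_hydrogen"
    LIGAND = "ligand"
    ION = "ion"


@dataclass
class AtomRecord:
    """A single atom with its nonbonded parameters.

    charge in e, lj_sigma in Å, lj_epsilon in kcal/mol.
    """

    atom_index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    role: AtomRole
    charge: float
    lj_sigma: float
    lj_epsilon: float

    def __post_init__(self) -> None:
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(
                f"negative LJ parameters for atom {self.atom_index} ({self.name})"
            )


@dataclass
class Topology:
    """Atoms, their molecule partition, and solute reference coordinates."""

    atoms: list[AtomRecord]
    molecules: list[list[int]]
    solute_reference_coordinates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        covered = sorted(i for mol in self.molecules for i in mol)
        if covered != list(range(len(self.atoms))):
            raise ValueError("molecule partition must cover all atoms exactly once")
        for mol in self.molecules:
            q = sum(self.atoms[i].charge for i in mol)
            if abs(q - round(q)) > 1e-6:
                raise ValueError(
                    f"molecule charge {q:.8f} is not integral (atoms {mol[:3]}...)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_with_role(self, *roles: AtomRole) -> np.ndarray:
        roleset = set(roles)
        return np.array(
            [a.atom_index for a in self.atoms if a.role in roleset], dtype=int
        )

    @property
    def water_molecules(self) -> list[list[int]]:
        """Molecules that are waters, each ordered [O, H, H]."""
        out = []
        for mol in self.molecules:
            roles = [self.atoms[i].role for i in mol]
            if AtomRole.WATER_OXYGEN in roles:
                o = [i for i in mol if self.atoms[i].role is AtomRole.WATER_OXYGEN]
                h = [i for i in mol if self.atoms[i].role is AtomRole.WATER_HYDROGEN]
                if len(o) != 1 or len(h) != 2:
                    raise ValueError(f"malformed water molecule: atoms {mol}")
                out.append([o[0]] + h)
        return out

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms])

    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])


@dataclass
class FrameSeries:
    """Per-frame coordinates (Å) with per-frame orthorhombic box lengths."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3) Å
    box_lengths: np.ndarray  # (n_frames, 3) Å
    weights: Optional[np.ndarray] = None  # (n_frames,), sums to 1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.box_lengths.ndim == 1:
            self.box_lengths = np.tile(self.box_lengths, (self.n_frames, 1))
        if self.box_lengths.shape != (self.n_frames, 3):
            raise ValueError("box_lengths must have shape (n_frames, 3)")
        if not np.all(self.box_lengths > 0):
            raise ValueError("all box lengths must be strictly positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_frames,):
                raise ValueError("weights must be per-frame")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def effective_weights(self) -> np.ndarray:
        """Per-frame weights, uniform when none were supplied."""
        if self.weights is None:
            return np.full(self.n_frames, 1.0 / self.n_frames)
        return self.weights / self.weights.sum()


@dataclass
class LigandPose:
    """Heavy-atom bound pose of a ligand."""

    heavy_atom_positions: np.ndarray  # (m, 3) Å
    vdw_radii: np.ndarray  # (m,) Å
    atom_names: list[str]

    def __post_init__(self) -> None:
        self.heavy_atom_positions = np.atleast_2d(
            np.asarray(self.heavy_atom_positions, dtype=float)
        )
        self.vdw_radii = np.atleast_1d(np.asarray(self.vdw_radii, dtype=float))
        if len(self.heavy_atom_positions) < 1:
            raise ValueError("ligand pose needs at least one heavy atom")
        if np.any(self.vdw_radii <= 0.5) or np.any(self.vdw_radii >= 3.0):
            raise ValueError("van der Waals radii must lie in (0.5, 3.0) Å")

    @property
    def n_atoms(self) -> int:
        return len(self.heavy_atom_positions)


@dataclass
class CrystalWaterSet:
    """Crystallographic water oxygen positions."""

    oxygen_positions: np.ndarray  # (k, 3) Å
    source_label: str = ""

    def __post_init__(self) -> None:
        self.oxygen_positions = np.asarray(self.oxygen_positions, dtype=float)
        if self.oxygen_positions.size == 0:
            self.oxygen_positions = np.zeros((0, 3))
        self.oxygen_positions = np.atleast_2d(self.oxygen_positions)

    def __len__(self) -> int:
        return len(self.oxygen_positions)


@dataclass
class WaterObservation:
    """One water in one frame: oxygen position and rigid-body orientation."""

    frame_index: int
    molecule_id: int
    oxygen_position: np.ndarray  # (3,) Å
    orientation: np.ndarray  # unit quaternion (w, x, y, z)


@dataclass
class SiteThermo:
    """Per-site IST energetic, entropic and structural averages."""

    Esw: float = 0.0
    Eww: float = 0.0
    Etot: float = 0.0
    Eww_nbr: float = 0.0
    minus_TSe_trans: Optional[float] = None
    minus_TSe_orient: Optional[float] = None
    minus_TSe: Optional[float] = None
    Nnbr: float = 0.0
    fenc: float = 0.0
    NswHB: float = 0.0
    NwwHB: float = 0.0
    fwwHB: float = 0.0
    Nww_lostHB: float = 0.0
    eww_nbr_defined: bool = True
    entropy_flagged: bool = False


@dataclass
class SiteLabels:
    env_class: str = ""  # A / P / C
    ww_class: str = ""  # En / Fr
    tot_class: str = ""  # F / U
    exposed: bool = False

    @property
    def composite(self) -> str:
        return f"{self.env_class}.{self.ww_class}.{self.tot_class}"


@dataclass
class HydrationSite:
    """A 1 Å-radius high-occupancy water site in the analysis region."""

    site_id: int
    center: np.ndarray  # (3,) Å
    fo: float
    member_observations: list[WaterObservation] = field(default_factory=list)
    thermo: SiteThermo = field(default_factory=SiteThermo)
    labels: SiteLabels = field(default_factory=SiteLabels)
    displaced: Optional[bool] = None

    @property
    def n_members(self) -> int:
        return len(self.member_observations)


@dataclass
class BulkReference:
    """Bulk-water reference constants used by classification and derived
    metrics.

    Defaults are the conventional TIP3P neat-liquid values at 300 K: total
    interaction energy per water (½ convention) −9.53 kcal/mol, per-neighbor
    water–water energy −1.36 kcal/mol, 5.26 first-shell neighbors, 3.33
    water–water hydrogen bonds, number density 0.0329 Å⁻³.
    """

    Etot_bulk: float = -9.53
    Eww_nbr_bulk: float = -1.36
    Nnbr_bulk: float = 5.26
    NwwHB_bulk: float = 3.33
    fwwHB_bulk: float = 0.63
    density: float = 0.0329
    temperature: float = 300.0

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class EnergyModel:
    """Truncated Coulomb + Lennard-Jones nonbonded model.

    Lorentz–Berthelot combining, per-pair cutoff, minimum image on an
    orthorhombic box. No long-range (Ewald) treatment: these are
    analysis-time interaction energies, not dynamics.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float = 10.0
    minimum_image: bool = True


@dataclass
class AnalysisRegion:
    """Region of space whose waters enter the analysis.

    Either a shell around a ligand pose (default 5 Å) or an explicit sphere.
    """

    mode: str = "sphere"  # "ligand_shell" | "sphere"
    ligand: Optional[LigandPose] = None
    shell_distance: float = 5.0
    sphere_center: Optional[np.ndarray] = None
    sphere_radius: float = 8.0

    def __post_init__(self) -> None:
        if self.mode not in ("ligand_shell", "sphere"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if self.mode == "ligand_shell" and self.ligand is None:
            raise ValueError("ligand_shell region requires a ligand pose")
        if self.mode == "sphere":
            if self.sphere_center is None:
                raise ValueError("sphere region requires a center")
            self.sphere_center = np.asarray(self.sphere_center, dtype=float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 3) inside the region (no imaging)."""
        points = np.atleast_2d(points)
        if self.mode == "sphere":
            d = np.linalg.norm(points - self.sphere_center, axis=1)
            return d <= self.sphere_radius
        d = np.linalg.norm(
            points[:, None, :] - self.ligand.heavy_atom_positions[None, :, :],
            axis=2,
        ).min(axis=1)
        return d <= self.shell_distance


def minimum_image_displacement(
    delta: np.ndarray, box_lengths: Optional[np.ndarray]
) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box_lengths is None:
        return delta
    return delta - box_lengths * np.round(delta / box_lengths)
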