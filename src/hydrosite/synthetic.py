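"""Synthetic pocket systems with planted hydration sites and known ground truth.

The generator emulates the statistical structure a restrained explicit-water
pocket simulation presents to the analysis stages: a rigid pseudo-receptor
whose atoms realize a chosen local-environment class at each planted site,
site waters drawn per frame with Bernoulli occupancy, Gaussian positional
spread and a configurable orientation distribution, and bulk-like background
waters sampled i.i.d. uniform at a target density. Because frames are
independent draws from the target ensemble, every estimator downstream has a
clean analytic or brute-force oracle.

Waters are rigid 3-site TIP3P molecules (O–H 0.9572 Å, H–O–H 104.52°,
qO = −0.834 e, qH = +0.417 e, LJ on oxygen only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    AtomRecord,
    AtomRole,
    CrystalWaterSet,
    EnergyModel,
    FrameSeries,
    LigandPose,
    Topology,
)

# TIP3P rigid geometry and parameters
TIP3P_OH = 0.9572  # Å
TIP3P_HOH = math.radians(104.52)
TIP3P_Q_O = -0.834
TIP3P_Q_H = 0.417
TIP3P_SIGMA_O = 3.1507  # Å
TIP3P_EPS_O = 0.1521  # kcal/mol

_ALPHA = TIP3P_HOH / 2.0
# body frame: O at origin, HOH bisector along +z, H–H axis along x
WATER_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],
        [TIP3P_OH * math.sin(_ALPHA), 0.0, TIP3P_OH * math.cos(_ALPHA)],
        [-TIP3P_OH * math.sin(_ALPHA), 0.0, TIP3P_OH * math.cos(_ALPHA)],
    ]
)

DEFAULT_BULK_DENSITY = 0.0329  # waters/Å³, ambient TIP3P
BACKGROUND_EXCLUSION = 2.4  # Å: background waters keep clear of site centers
CLASS_ATOM_DISTANCE = 3.0  # Å from site center to its class-realizing atom
LIGAND_ATOM_RADIUS = 1.70  # Å, carbon-like probe atoms

RESIDUE_CLASSES = ("apolar", "polar", "charged")


@dataclass
class SiteSpec:
    """Specification of one planted hydration site."""

    center: np.ndarray
    occupancy_target: float = 1.0
    positional_sigma: float = 0.2  # Å
    orientation_mode: str = "uniform"  # uniform | fixed | vmf
    vmf_kappa: float = 10.0
    nearest_residue_class: str = "apolar"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not 0.0 < self.occupancy_target <= 1.0:
            raise ValueError("occupancy_target must lie in (0, 1]")
        if self.positional_sigma <= 0:
            raise ValueError("positional_sigma must be positive")
        if self.orientation_mode not in ("uniform", "fixed", "vmf"):
            raise ValueError(f"unknown orientation mode {self.orientation_mode!r}")
        if self.nearest_residue_class not in RESIDUE_CLASSES:
            raise ValueError(
                f"unknown residue class {self.nearest_residue_class!r}"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    site_specs: list[SiteSpec]
    bulk_density: float
    site_presence: np.ndarray  # (n_sites, n_frames) bool
    site_molecule_ids: list[int]  # molecule index of each planted site water
    planted_crystal_waters: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3))
    )
    box_lengths: Optional[np.ndarray] = None

    def planted_occupancies(self) -> np.ndarray:
        return self.site_presence.mean(axis=1)

    def brute_force_water_energies(self, topology, coordinates, box, model=None):
        """Exact per-water energies for one frame (oracle path)."""
        return brute_force_water_energies(
            topology, coordinates, box, model or EnergyModel()
        )


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention: w, x, y, z)

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations: normalized 4D Gaussians."""
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def sample_vmf_quaternions(
    n: int, mu: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """von Mises–Fisher samples on S³ around mean quaternion mu (Wood 1994)."""
    d = 4
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    b = (-2 * kappa + math.sqrt(4 * kappa**2 + (d - 1) ** 2)) / (d - 1)
    x0 = (1 - b) / (1 + b)
    c = kappa * x0 + (d - 1) * math.log(1 - x0**2)
    samples = np.empty((n, d))
    for i in range(n):
        while True:
            z = rng.beta((d - 1) / 2.0, (d - 1) / 2.0)
            w = (1 - (1 + b) * z) / (1 - (1 - b) * z)
            u = rng.uniform()
            if kappa * w + (d - 1) * math.log(1 - x0 * w) - c >= math.log(u):
                break
        v = rng.standard_normal(d - 1)
        v /= np.linalg.norm(v)
        samples[i, 0] = w
        samples[i, 1:] = math.sqrt(max(0.0, 1 - w * w)) * v
    # Householder reflection mapping e1 onto mu
    e1 = np.zeros(d)
    e1[0] = 1.0
    u = e1 - mu
    norm = np.linalg.norm(u)
    if norm > 1e-12:
        u /= norm
        samples = samples - 2.0 * np.outer(samples @ u, u)
    return samples


def water_coordinates(center: np.ndarray, quaternion: np.ndarray) -> np.ndarray:
    """Place a rigid TIP3P water: rotate the template and translate the O."""
    rot = quat_to_matrix(quaternion)
    return center + WATER_TEMPLATE @ rot.T


# ---------------------------------------------------------------------------
# brute-force energy oracle (scalar arithmetic, independent of the
# vectorized implementation in site_thermo)

def brute_force_pair_energy(
    ri, rj, qi, qj, si, sj, ei, ej, box, cutoff, coulomb_constant=332.0636
) -> float:
    dx = [ri[k] - rj[k] for k in range(3)]
    if box is not None:
        for k in range(3):
            dx[k] -= box[k] * round(dx[k] / box[k])
    r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
    if r == 0:
        raise ValueError("zero interatomic distance")
    if r > cutoff:
        return 0.0
    energy = coulomb_constant * qi * qj / r
    eps = math.sqrt(ei * ej)
    if eps > 0:
        sigma = 0.5 * (si + sj)
        sr6 = (sigma / r) ** 6
        energy += 4.0 * eps * (sr6 * sr6 - sr6)
    return energy


def brute_force_molecule_pair_energy(
    topology: Topology,
    coordinates: np.ndarray,
    mol_a: Sequence[int],
    mol_b: Sequence[int],
    box,
    model: EnergyModel,
) -> float:
    total = 0.0
    for i in mol_a:
        ai = topology.atoms[i]
        for j in mol_b:
            aj = topology.atoms[j]
            total += brute_force_pair_energy(
                coordinates[i], coordinates[j], ai.charge, aj.charge,
                ai.lj_sigma, aj.lj_sigma, ai.lj_epsilon, aj.lj_epsilon,
                box if model.minimum_image else None, model.cutoff,
                model.coulomb_constant,
            )
    return total


def brute_force_water_energies(
    topology: Topology,
    coordinates: np.ndarray,
    box,
    model: EnergyModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-water (Esw, Eww) for one frame by double loop.

    Esw sums interactions with every solute/ligand/ion atom; Eww carries the
    ½ pair-sharing convention.
    """
    waters = topology.water_molecules
    other_idx = [
        a.atom_index
        for a in topology.atoms
        if a.role in (AtomRole.SOLUTE, AtomRole.LIGAND, AtomRole.ION)
    ]
    esw = np.zeros(len(waters))
    eww = np.zeros(len(waters))
    for wi, mol in enumerate(waters):
        esw[wi] = brute_force_molecule_pair_energy(
            topology, coordinates, mol, other_idx, box, model
        )
    for wi in range(len(waters)):
        for wj in range(wi + 1, len(waters)):
            e = brute_force_molecule_pair_energy(
                topology, coordinates, waters[wi], waters[wj], box, model
            )
            eww[wi] += 0.5 * e
            eww[wj] += 0.5 * e
    return esw, eww


# ---------------------------------------------------------------------------
# topology assembly

def _water_atoms(start_index: int, residue_index: int) -> list[AtomRecord]:
    spec = [
        ("O", "O", AtomRole.WATER_OXYGEN, TIP3P_Q_O, TIP3P_SIGMA_O, TIP3P_EPS_O),
        ("H1", "H", AtomRole.WATER_HYDROGEN, TIP3P_Q_H, 0.0, 0.0),
        ("H2", "H", AtomRole.WATER_HYDROGEN, TIP3P_Q_H, 0.0, 0.0),
    ]
    return [
        AtomRecord(start_index + k, name, element, "HOH", residue_index, "0",
                   role, q, s, e)
        for k, (name, element, role, q, s, e) in enumerate(spec)
    ]


def _class_atoms(
    spec: SiteSpec, direction: np.ndarray, start_index: int, residue_index: int
) -> tuple[list[AtomRecord], np.ndarray]:
    """Pseudo-atoms realizing a residue class near a site center."""
    base = spec.center + CLASS_ATOM_DISTANCE * direction
    if spec.nearest_residue_class == "apolar":
        atoms = [AtomRecord(start_index, "C1", "C", "PKA", residue_index, "0",
                            AtomRole.SOLUTE, 0.0, 3.4, 0.1)]
        positions = base[None, :]
    elif spec.nearest_residue_class == "polar":
        # ±0.4 e dipole: the O end faces the site, the counter charge sits
        # radially outward beyond the 3.5 Å environment cutoff
        outer = spec.center + (CLASS_ATOM_DISTANCE + 1.2) * direction
        atoms = [
            AtomRecord(start_index, "OD1", "O", "PKP", residue_index, "0",
                       AtomRole.SOLUTE, -0.4, 3.0, 0.17),
            AtomRecord(start_index + 1, "CG", "C", "PKP", residue_index, "0",
                       AtomRole.SOLUTE, 0.4, 3.4, 0.1),
        ]
        positions = np.vstack([base, outer])
    else:  # charged
        atoms = [AtomRecord(start_index, "NZ", "N", "PKC", residue_index, "0",
                            AtomRole.SOLUTE, 1.0, 3.25, 0.17)]
        positions = base[None, :]
    return atoms, positions


def _validate_site_environments(specs: Sequence[SiteSpec],
                                solute_positions: np.ndarray,
                                solute_atoms: Sequence[AtomRecord]) -> None:
    """Every planted center must see exactly its own class within 3.5 Å."""
    rank = {"apolar": 0, "polar": 1, "charged": 2}
    for spec in specs:
        d = np.linalg.norm(solute_positions - spec.center, axis=1)
        near = np.where(d <= 3.5)[0]
        if len(near) == 0:
            raise ValueError(f"no pocket atom within 3.5 Å of site {spec.center}")
        classes = []
        for i in near:
            a = solute_atoms[i]
            if abs(a.charge) >= 0.9:
                classes.append("charged")
            elif a.element in ("N", "O", "S") or abs(a.charge) >= 0.3:
                classes.append("polar")
            else:
                classes.append("apolar")
        realized = max(classes, key=lambda c: rank[c])
        if realized != spec.nearest_residue_class:
            raise ValueError(
                "infeasible geometry: site at "
                f"{np.round(spec.center, 2)} realizes {realized!r} instead of "
                f"{spec.nearest_residue_class!r}; separate the site centers"
            )


def generate_pocket_system(
    specs: Sequence[SiteSpec],
    n_frames: int,
    n_background_waters: int,
    seed: int,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    n_scaffold_atoms: int = 4,
) -> tuple[Topology, FrameSeries, GroundTruth]:
    """Generate a rigid pseudo-pocket with planted hydration sites.

    Site waters appear per frame with Bernoulli(occupancy) at Gaussian
    positions around their centers; in frames where a site is vacant its
    water is relocated into the bulk so the atom count stays constant.
    Background waters are i.i.d. uniform at ``bulk_density``, excluded
    within 2.4 Å of planted centers.
    """
    specs = list(specs)
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    if not specs:
        raise ValueError("at least one site spec is required")
    centers = np.array([s.center for s in specs])
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            if np.linalg.norm(centers[i] - centers[j]) < 3.0:
                raise ValueError(
                    f"site centers {i} and {j} are closer than 3 Å"
                )
    if not 0.02 < bulk_density < 0.05:
        raise ValueError("bulk_density outside the liquid-water range")

    rng = np.random.default_rng(seed)
    pocket_center = centers.mean(axis=0)

    # rigid pocket atoms
    solute_atoms: list[AtomRecord] = []
    solute_positions: list[np.ndarray] = []
    molecules: list[list[int]] = []
    idx = 0
    for si, spec in enumerate(specs):
        others = np.delete(centers, si, axis=0)
        if len(others):
            direction = spec.center - others.mean(axis=0)
        else:
            direction = np.array([1.0, 0.0, 0.0])
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        atoms, positions = _class_atoms(spec, direction, idx, si)
        solute_atoms.extend(atoms)
        solute_positions.extend(positions)
        molecules.append([a.atom_index for a in atoms])
        idx += len(atoms)
    # apolar scaffold ring completing the rigid pocket
    n_res = len(specs)
    for k in range(n_scaffold_atoms):
        angle = 2 * math.pi * k / max(n_scaffold_atoms, 1)
        pos = pocket_center + np.array(
            [4.5 * math.cos(angle), 4.5 * math.sin(angle), 4.5]
        )
        if np.min(np.linalg.norm(centers - pos, axis=1)) <= 3.6:
            pos = pos + np.array([0.0, 0.0, 1.5])
        solute_atoms.append(
            AtomRecord(idx, "C1", "C", "PKT", n_res + k, "0",
                       AtomRole.SOLUTE, 0.0, 3.4, 0.1)
        )
        solute_positions.append(pos)
        molecules.append([idx])
        idx += 1
    solute_positions = np.array(solute_positions)
    _validate_site_environments(specs, solute_positions, solute_atoms)

    edge = (max(n_background_waters, 1) / bulk_density) ** (1.0 / 3.0)
    extent = max(
        np.abs(solute_positions - pocket_center).max(),
        np.abs(centers - pocket_center).max(),
    )
    if extent + 1.0 > edge / 2.0:
        raise ValueError(
            "box too small for the requested background count at this density"
        )
    box = np.array([edge, edge, edge])
    lo = pocket_center - edge / 2.0
    hi = pocket_center + edge / 2.0

    # waters: one molecule per planted site, then the background
    atoms = list(solute_atoms)
    site_molecule_ids = []
    n_solute_res = n_res + n_scaffold_atoms
    for si in range(len(specs)):
        site_molecule_ids.append(len(molecules))
        recs = _water_atoms(idx, n_solute_res + si)
        atoms.extend(recs)
        molecules.append([r.atom_index for r in recs])
        idx += 3
    for bi in range(n_background_waters):
        recs = _water_atoms(idx, n_solute_res + len(specs) + bi)
        atoms.extend(recs)
        molecules.append([r.atom_index for r in recs])
        idx += 3

    topology = Topology(atoms=atoms, molecules=molecules)
    topology.solute_reference_coordinates = solute_positions.copy()

    def bulk_position() -> np.ndarray:
        for _ in range(1000):
            p = rng.uniform(lo, hi)
            if np.min(np.linalg.norm(centers - p, axis=1)) >= BACKGROUND_EXCLUSION:
                return p
        raise RuntimeError("could not place a background water")

    n_atoms = len(atoms)
    coords = np.empty((n_frames, n_atoms, 3))
    presence = np.zeros((len(specs), n_frames), dtype=bool)
    for f in range(n_frames):
        coords[f, : len(solute_atoms)] = solute_positions
        cursor = len(solute_atoms)
        for si, spec in enumerate(specs):
            present = rng.uniform() < spec.occupancy_target
            presence[si, f] = present
            if present:
                pos = spec.center + spec.positional_sigma * rng.standard_normal(3)
            else:
                pos = bulk_position()
            if spec.orientation_mode == "fixed":
                q = np.array([1.0, 0.0, 0.0, 0.0])
            elif spec.orientation_mode == "vmf":
                q = sample_vmf_quaternions(
                    1, np.array([1.0, 0.0, 0.0, 0.0]), spec.vmf_kappa, rng
                )[0]
            else:
                q = random_unit_quaternions(1, rng)[0]
            coords[f, cursor : cursor + 3] = water_coordinates(pos, q)
            cursor += 3
        for _ in range(n_background_waters):
            pos = bulk_position()
            q = random_unit_quaternions(1, rng)[0]
            coords[f, cursor : cursor + 3] = water_coordinates(pos, q)
            cursor += 3

    frames = FrameSeries(coordinates=coords, box_lengths=np.tile(box, (n_frames, 1)))
    truth = GroundTruth(
        site_specs=specs,
        bulk_density=bulk_density,
        site_presence=presence,
        site_molecule_ids=site_molecule_ids,
        box_lengths=box,
    )
    return topology, frames, truth


def generate_bulk_box(
    density: float,
    n_waters: int,
    n_frames: int,
    seed: int,
) -> tuple[Topology, FrameSeries]:
    """Ideal-gas-like box of rigid waters, i.i.d. uniform per frame."""
    if density <= 0:
        raise ValueError("density must be positive")
    if n_waters < 2:
        raise ValueError("need at least two waters")
    rng = np.random.default_rng(seed)
    edge = (n_waters / density) ** (1.0 / 3.0)
    box = np.array([edge, edge, edge])

    atoms: list[AtomRecord] = []
    molecules: list[list[int]] = []
    for wi in range(n_waters):
        recs = _water_atoms(3 * wi, wi)
        atoms.extend(recs)
        molecules.append([r.atom_index for r in recs])
    topology = Topology(atoms=atoms, molecules=molecules)

    coords = np.empty((n_frames, 3 * n_waters, 3))
    for f in range(n_frames):
        positions = rng.uniform(0.0, edge, size=(n_waters, 3))
        quats = random_unit_quaternions(n_waters, rng)
        for wi in range(n_waters):
            coords[f, 3 * wi : 3 * wi + 3] = water_coordinates(
                positions[wi], quats[wi]
            )
    frames = FrameSeries(coordinates=coords, box_lengths=np.tile(box, (n_frames, 1)))
    return topology, frames


def generate_ligand_and_crystal(
    specs: Sequence[SiteSpec],
    displace_subset: Sequence[int],
    probe: float = 1.5,
    crystal_site_indices: Optional[Sequence[int]] = None,
    n_decoys: int = 0,
    seed: int = 0,
) -> tuple[LigandPose, CrystalWaterSet]:
    """Place ligand atoms so exactly ``displace_subset`` sites are displaced.

    A carbon-like atom (r_vdw 1.7 Å) is dropped 0.5 Å off each chosen
    center, so the site is displaced in both the envelope and the
    center-distance reading of the probe criterion; every other center is
    kept outside the expanded envelope by at least 0.5 Å. Crystal waters are
    planted exactly at the requested site centers plus random decoys more
    than 2 Å from every center.
    """
    specs = list(specs)
    centers = np.array([s.center for s in specs])
    displace_subset = sorted(set(int(i) for i in displace_subset))
    if any(i < 0 or i >= len(specs) for i in displace_subset):
        raise ValueError("displace_subset contains an invalid site index")
    rng = np.random.default_rng(seed)
    pocket_center = centers.mean(axis=0)

    positions, names = [], []
    if displace_subset:
        for k, si in enumerate(displace_subset):
            positions.append(centers[si] + np.array([0.0, 0.0, 0.5]))
            names.append(f"C{k + 1}")
    else:
        positions.append(pocket_center + np.array([0.0, 0.0, 4.0]))
        names.append("C1")
    positions = np.array(positions)

    retained = [i for i in range(len(specs)) if i not in displace_subset]
    clearance = probe + LIGAND_ATOM_RADIUS + 0.5
    for si in retained:
        if np.min(np.linalg.norm(positions - centers[si], axis=1)) < clearance:
            raise ValueError(
                f"infeasible geometry: retained site {si} falls inside the "
                f"ligand envelope margin; increase center separation"
            )
    pose = LigandPose(
        positions, np.full(len(positions), LIGAND_ATOM_RADIUS), names
    )

    crystal_positions = []
    if crystal_site_indices:
        for si in crystal_site_indices:
            crystal_positions.append(centers[int(si)])
    for _ in range(n_decoys):
        for _attempt in range(1000):
            base = positions[rng.integers(len(positions))]
            p = base + rng.uniform(-4.0, 4.0, size=3)
            if np.min(np.linalg.norm(centers - p, axis=1)) > 2.0:
                crystal_positions.append(p)
                break
        else:
            raise RuntimeError("could not place a decoy crystal water")
    crystal = CrystalWaterSet(
        np.array(crystal_positions) if crystal_positions else np.zeros((0, 3)),
        source_label="synthetic",
    )
    return pose, crystal
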