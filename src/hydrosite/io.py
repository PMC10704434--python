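"""Readers and writers for every external representation the pipeline touches.

Trajectories are accepted as multi-model PDB (the portable baseline dialect)
or as DCD/XTC next to a PDB topology; all three go through mdtraj and are
converted to Å at the boundary (mdtraj works in nm). Nonbonded parameters
(charges in e, LJ sigma in Å, epsilon in kcal/mol) live in a JSON sidecar
keyed by (residue name, atom name) or by absolute atom index.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import mdtraj as md
import numpy as np
import pandas as pd
from mdtraj.core import element as md_element

from .core import (
    AtomRecord,
    AtomRole,
    CrystalWaterSet,
    FrameSeries,
    HydrationSite,
    LigandPose,
    Topology,
)

WATER_RESIDUE_NAMES = ("HOH", "WAT", "TIP3")
DEFAULT_LIGAND_RESIDUE_NAMES = ("LIG",)
ION_ELEMENTS = ("Na", "K", "Cl", "Mg", "Ca", "Zn", "Br", "I", "F", "Li")

# van der Waals radii (Å) for ligand heavy atoms read from bare PDB files
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

SITE_TABLE_COLUMNS = [
    "site_id", "x", "y", "z", "fo", "Esw", "Eww", "Etot", "Eww_nbr",
    "minus_TSe_trans", "minus_TSe_orient", "minus_TSe", "Nnbr", "fenc",
    "NswHB", "NwwHB", "fwwHB", "Nww_lostHB",
    "env_class", "ww_class", "tot_class", "displaced",
]


# ---------------------------------------------------------------------------
# topology

def _load_parameters(params_path: Path) -> tuple[dict, dict]:
    with open(params_path) as fh:
        data = json.load(fh)
    by_key: dict[tuple[str, str], dict] = {}
    by_index: dict[int, dict] = {}
    for entry in data.get("atoms", []):
        if "index" in entry:
            by_index[int(entry["index"])] = entry
        else:
            by_key[(entry["residue"], entry["name"])] = entry
    return by_key, by_index


def read_topology(
    pdb_path: str | Path,
    params_path: str | Path,
    water_residue_names: Sequence[str] = WATER_RESIDUE_NAMES,
    ligand_residue_names: Sequence[str] = DEFAULT_LIGAND_RESIDUE_NAMES,
) -> Topology:
    """Read a PDB topology plus its JSON parameter sidecar.

    Roles are assigned from residue names (waters), the configured ligand
    residue names, and single-atom ion residues; everything else is solute.
    The molecule partition groups atoms by residue.
    """
    traj = md.load(str(pdb_path))
    if traj.n_atoms == 0:
        raise ValueError(f"no atoms in {pdb_path}")
    by_key, by_index = _load_parameters(Path(params_path))

    atoms: list[AtomRecord] = []
    molecules: list[list[int]] = []
    for residue in traj.topology.residues:
        mol = []
        is_water = residue.name in water_residue_names
        res_atoms = list(residue.atoms)
        if is_water and len(res_atoms) != 3:
            raise ValueError(
                f"water residue {residue.name} {residue.resSeq} has "
                f"{len(res_atoms)} atoms, expected 3"
            )
        for atom in res_atoms:
            element = atom.element.symbol if atom.element is not None else ""
            if is_water:
                role = (
                    AtomRole.WATER_OXYGEN
                    if element == "O"
                    else AtomRole.WATER_HYDROGEN
                )
            elif residue.name in ligand_residue_names:
                role = AtomRole.LIGAND
            elif len(res_atoms) == 1 and element in ION_ELEMENTS:
                role = AtomRole.ION
            else:
                role = AtomRole.SOLUTE
            entry = by_index.get(atom.index) or by_key.get((residue.name, atom.name))
            if entry is None:
                raise ValueError(
                    f"missing nonbonded parameters for atom {atom.index} "
                    f"({residue.name}/{atom.name})"
                )
            atoms.append(
                AtomRecord(
                    atom_index=atom.index,
                    name=atom.name,
                    element=element,
                    residue_name=residue.name,
                    residue_index=residue.index,
                    chain_id=str(residue.chain.index),
                    role=role,
                    charge=float(entry["charge"]),
                    lj_sigma=float(entry["sigma"]),
                    lj_epsilon=float(entry["epsilon"]),
                )
            )
            mol.append(atom.index)
        molecules.append(mol)

    topology = Topology(atoms=atoms, molecules=molecules)
    solute_idx = [
        a.atom_index
        for a in atoms
        if a.role in (AtomRole.SOLUTE, AtomRole.ION, AtomRole.LIGAND)
    ]
    if solute_idx:
        topology.solute_reference_coordinates = traj.xyz[0, solute_idx] * 10.0
    return topology


def write_parameters_json(topology: Topology, path: str | Path) -> None:
    entries = [
        {
            "index": a.atom_index,
            "residue": a.residue_name,
            "name": a.name,
            "charge": a.charge,
            "sigma": a.lj_sigma,
            "epsilon": a.lj_epsilon,
        }
        for a in topology.atoms
    ]
    with open(path, "w") as fh:
        json.dump({"atoms": entries}, fh, indent=1)


def _to_mdtraj_topology(topology: Topology) -> md.Topology:
    top = md.Topology()
    chain = top.add_chain()
    atom_order = []
    for mol in topology.molecules:
        first = topology.atoms[mol[0]]
        residue = top.add_residue(first.residue_name, chain)
        for i in mol:
            rec = topology.atoms[i]
            try:
                elem = md_element.get_by_symbol(rec.element)
            except KeyError:
                elem = md_element.virtual
            top.add_atom(rec.name, elem, residue)
            atom_order.append(i)
    if atom_order != list(range(topology.n_atoms)):
        raise ValueError("molecule partition must be contiguous for PDB output")
    return top


def _to_mdtraj_trajectory(frames: FrameSeries, topology: Topology) -> md.Trajectory:
    top = _to_mdtraj_topology(topology)
    return md.Trajectory(
        xyz=frames.coordinates / 10.0,
        topology=top,
        unitcell_lengths=frames.box_lengths / 10.0,
        unitcell_angles=np.full((frames.n_frames, 3), 90.0),
    )


def write_trajectory(
    frames: FrameSeries,
    topology: Topology,
    path: str | Path,
    dialect: str = "multi_model_pdb",
) -> None:
    traj = _to_mdtraj_trajectory(frames, topology)
    path = str(path)
    if dialect == "multi_model_pdb":
        traj.save_pdb(path)
    elif dialect == "dcd":
        traj.save_dcd(path)
    elif dialect == "xtc":
        traj.save_xtc(path)
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")


def write_topology_pdb(
    topology: Topology, coordinates: np.ndarray, path: str | Path,
    box_lengths: Optional[np.ndarray] = None,
) -> None:
    """Write a single-frame PDB of the system (topology reference frame)."""
    box = np.asarray(box_lengths if box_lengths is not None else [999.0] * 3)
    frames = FrameSeries(coordinates[None, :, :], box[None, :])
    write_trajectory(frames, topology, path, "multi_model_pdb")


def read_trajectory(
    path: str | Path,
    topology: Topology,
    dialect: str = "multi_model_pdb",
) -> FrameSeries:
    """Read a trajectory in any supported dialect into Å coordinates."""
    path = str(path)
    if dialect == "multi_model_pdb":
        traj = md.load(path)
    elif dialect == "dcd":
        traj = md.load_dcd(path, top=_to_mdtraj_topology(topology))
    elif dialect == "xtc":
        traj = md.load_xtc(path, top=_to_mdtraj_topology(topology))
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")
    if traj.n_frames == 0:
        raise ValueError(f"zero frames in {path}")
    if traj.n_atoms != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {traj.n_atoms}, "
            f"topology has {topology.n_atoms}"
        )
    if traj.unitcell_lengths is None:
        raise ValueError(f"trajectory {path} carries no box information")
    return FrameSeries(
        coordinates=traj.xyz * 10.0,
        box_lengths=traj.unitcell_lengths * 10.0,
    )


# ---------------------------------------------------------------------------
# ligand pose / crystal waters

def read_ligand_pose(path: str | Path) -> LigandPose:
    """Read a bound ligand pose (heavy atoms only) from a PDB file."""
    traj = md.load(str(path))
    positions, radii, names = [], [], []
    for atom in traj.topology.atoms:
        symbol = atom.element.symbol if atom.element is not None else ""
        if symbol == "H":
            continue
        positions.append(traj.xyz[0, atom.index] * 10.0)
        radii.append(VDW_RADII.get(symbol, DEFAULT_VDW_RADIUS))
        names.append(atom.name)
    if not positions:
        raise ValueError(f"no heavy atoms in ligand file {path}")
    return LigandPose(np.array(positions), np.array(radii), names)


def write_ligand_pose(pose: LigandPose, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (pos, name) in enumerate(zip(pose.heavy_atom_positions, pose.atom_names)):
            element = "".join(c for c in name if c.isalpha())[:1] or "C"
            fh.write(
                f"HETATM{i + 1:5d} {name:<4s} LIG A   1    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {element:>2s}\n"
            )
        fh.write("END\n")


def read_crystal_waters(path: str | Path, source_label: str = "") -> CrystalWaterSet:
    """Read crystallographic water oxygens (HOH O records) from a PDB."""
    traj = md.load(str(path))
    positions = [
        traj.xyz[0, a.index] * 10.0
        for a in traj.topology.atoms
        if a.residue.name in WATER_RESIDUE_NAMES
        and a.element is not None
        and a.element.symbol == "O"
    ]
    return CrystalWaterSet(np.array(positions) if positions else np.zeros((0, 3)),
                           source_label or str(path))


def write_crystal_waters(waters: CrystalWaterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, pos in enumerate(waters.oxygen_positions):
            fh.write(
                f"HETATM{i + 1:5d} O    HOH A{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"           O\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# per-frame TSV (binding coordinate / weights) and site table

def read_frame_series_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-frame TSV with columns frame_index, x [, weight]."""
    df = pd.read_csv(path, sep="\t")
    if "frame_index" not in df.columns or "x" not in df.columns:
        raise ValueError("per-frame TSV needs columns 'frame_index' and 'x'")
    return df


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "nan"
    return f"{value:.4f}"


def write_site_table(sites: Sequence[HydrationSite], path: str | Path) -> None:
    """Write the per-site summary TSV, rows sorted by occupancy descending."""
    if not sites:
        raise ValueError("site list is empty")
    rows = []
    for site in sorted(sites, key=lambda s: -s.fo):
        t, lab = site.thermo, site.labels
        rows.append([
            str(site.site_id),
            _fmt(site.center[0]), _fmt(site.center[1]), _fmt(site.center[2]),
            _fmt(site.fo), _fmt(t.Esw), _fmt(t.Eww), _fmt(t.Etot),
            _fmt(t.Eww_nbr), _fmt(t.minus_TSe_trans), _fmt(t.minus_TSe_orient),
            _fmt(t.minus_TSe), _fmt(t.Nnbr), _fmt(t.fenc), _fmt(t.NswHB),
            _fmt(t.NwwHB), _fmt(t.fwwHB), _fmt(t.Nww_lostHB),
            lab.env_class, lab.ww_class, lab.tot_class,
            "" if site.displaced is None else str(int(site.displaced)),
        ])
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_site_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
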