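"""Per-site IST energetics, entropy and structural averages.

Energies use a truncated Coulomb + Lennard-Jones model (Lorentz–Berthelot
combining, per-pair 10 Å cutoff, minimum image). Water–water energies carry
the ½ pair-sharing convention so the bulk per-water total matches the
conventional TIP3P value of −9.53 kcal/mol.

Excess entropies are estimated with first-nearest-neighbor estimators: in
translation over the member oxygen cloud relative to bulk water at its
number density, and in orientation over the member rigid-body rotations
relative to the uniform (Haar) distribution on SO(3). Both estimators are
calibrated so that bulk-like input yields zero; see ``site_entropy``.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AtomRecord,
    AtomRole,
    BulkReference,
    EnergyModel,
    FrameSeries,
    HydrationSite,
    SiteThermo,
    Topology,
    minimum_image_displacement,
)

EULER_GAMMA = float(np.euler_gamma)

NEIGHBOR_CUTOFF = 3.5  # Å O–O, first minimum of the water g(r)
HB_DISTANCE = 3.5  # Å donor–acceptor heavy-atom distance
HB_ANGLE_DEG = 30.0  # H–O···O alignment at the donor
ENTROPY_FLOOR_KB = -10.0  # per-term clip for degenerate distributions
N_MIN_OBSERVATIONS = 50


# ---------------------------------------------------------------------------
# pairwise energies

def pair_energy(atom_i: AtomRecord, atom_j: AtomRecord, r: float,
                model: Optional[EnergyModel] = None) -> float:
    """Nonbonded energy of one atom pair at separation r (Å)."""
    model = model or EnergyModel()
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    if r > model.cutoff:
        return 0.0
    energy = model.coulomb_constant * atom_i.charge * atom_j.charge / r
    eps = math.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    if eps > 0:
        sigma = 0.5 * (atom_i.lj_sigma + atom_j.lj_sigma)
        sr6 = (sigma / r) ** 6
        energy += 4.0 * eps * (sr6 * sr6 - sr6)
    return energy


def group_interaction_energy(
    pos_a: np.ndarray, pos_b: np.ndarray,
    q_a: np.ndarray, q_b: np.ndarray,
    sig_a: np.ndarray, sig_b: np.ndarray,
    eps_a: np.ndarray, eps_b: np.ndarray,
    box: Optional[np.ndarray],
    model: EnergyModel,
) -> np.ndarray:
    """Pairwise energy matrix (na, nb) between two atom groups."""
    delta = pos_a[:, None, :] - pos_b[None, :, :]
    if model.minimum_image and box is not None:
        delta = minimum_image_displacement(delta, box)
    r = np.sqrt((delta**2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = model.coulomb_constant * np.outer(q_a, q_b) / r
        eps = np.sqrt(np.outer(eps_a, eps_b))
        sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
        sr6 = (sigma / r) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
    energy = np.where(r > model.cutoff, 0.0, coul + lj)
    return np.nan_to_num(energy, nan=0.0, posinf=np.inf)


def _molecule_arrays(topology: Topology, indices: np.ndarray):
    return (
        topology.charges()[indices],
        topology.lj_sigmas()[indices],
        topology.lj_epsilons()[indices],
    )


def site_energies(
    site: HydrationSite,
    frames: FrameSeries,
    topology: Topology,
    model: Optional[EnergyModel] = None,
    neighbor_cutoff: float = NEIGHBOR_CUTOFF,
) -> tuple[float, float, float, float]:
    """Mean (Esw, Eww, Eww_nbr, Nnbr) over the site's member waters.

    Per member water: Esw sums interactions with every solute, ligand and
    ion atom; Eww is ½ the interaction with all other waters; the first
    shell holds water oxygens within ``neighbor_cutoff`` (minimum image);
    Eww_nbr is the per-member ratio (½ Σ first-shell energy)/Nnbr averaged
    over members that have neighbors.
    """
    if site.n_members == 0:
        raise ValueError("site has no member observations")
    model = model or EnergyModel()
    waters = topology.water_molecules
    mol_of_water = {}
    for w, mol in enumerate(waters):
        # molecule id = index into topology.molecules
        mol_of_water[_molecule_id(topology, mol)] = w
    water_atom_idx = np.array([i for mol in waters for i in mol])
    oxygen_idx = np.array([mol[0] for mol in waters])
    other_idx = topology.indices_with_role(
        AtomRole.SOLUTE, AtomRole.LIGAND, AtomRole.ION
    )
    qw, sw_, ew = _molecule_arrays(topology, water_atom_idx)
    qo, so, eo = (
        _molecule_arrays(topology, other_idx)
        if len(other_idx)
        else (np.zeros(0), np.zeros(0), np.zeros(0))
    )

    by_frame: dict[int, list[int]] = {}
    for obs in site.member_observations:
        by_frame.setdefault(obs.frame_index, []).append(obs.molecule_id)

    esw_vals, eww_vals, nnbr_vals, ewwnbr_vals = [], [], [], []
    n_waters = len(waters)
    for f, mol_ids in sorted(by_frame.items()):
        coords = frames.coordinates[f]
        box = frames.box_lengths[f]
        wpos = coords[water_atom_idx].reshape(n_waters, 3, 3)
        opos = coords[oxygen_idx]
        for mol_id in mol_ids:
            w = mol_of_water[mol_id]
            mpos = wpos[w].reshape(3, 3)
            mq, ms, me = qw[3 * w : 3 * w + 3], sw_[3 * w : 3 * w + 3], ew[3 * w : 3 * w + 3]
            if len(other_idx):
                esw = group_interaction_energy(
                    mpos, coords[other_idx], mq, qo, ms, so, me, eo, box, model
                ).sum()
            else:
                esw = 0.0
            pair_matrix = group_interaction_energy(
                mpos, coords[water_atom_idx], mq, qw, ms, sw_, me, ew, box, model
            )
            per_molecule = pair_matrix.reshape(3, n_waters, 3).sum(axis=(0, 2))
            per_molecule[w] = 0.0
            eww = 0.5 * per_molecule.sum()

            delta = minimum_image_displacement(opos - opos[w], box)
            oo = np.sqrt((delta**2).sum(axis=1))
            nbr = (oo <= neighbor_cutoff) & (np.arange(n_waters) != w)
            nnbr = int(nbr.sum())
            esw_vals.append(esw)
            eww_vals.append(eww)
            nnbr_vals.append(nnbr)
            if nnbr > 0:
                ewwnbr_vals.append(0.5 * per_molecule[nbr].sum() / nnbr)

    eww_nbr = float(np.mean(ewwnbr_vals)) if ewwnbr_vals else 0.0
    site.thermo.eww_nbr_defined = bool(ewwnbr_vals)
    return (
        float(np.mean(esw_vals)),
        float(np.mean(eww_vals)),
        eww_nbr,
        float(np.mean(nnbr_vals)),
    )


def _molecule_id(topology: Topology, mol: Sequence[int]) -> int:
    # molecule ids are positions in topology.molecules; cache on first use
    if not hasattr(topology, "_mol_id_cache"):
        topology._mol_id_cache = {tuple(m): i for i, m in enumerate(topology.molecules)}
    return topology._mol_id_cache[tuple(mol)]


# ---------------------------------------------------------------------------
# hydrogen bonds

def _donor_aligned(o_donor, h_positions, o_acceptor, box, cos_limit) -> bool:
    oa = minimum_image_displacement(o_acceptor - o_donor, box)
    noa = np.linalg.norm(oa)
    if noa == 0:
        return False
    for h in h_positions:
        oh = minimum_image_displacement(h - o_donor, box)
        noh = np.linalg.norm(oh)
        if noh == 0:
            continue
        if np.dot(oh, oa) / (noh * noa) >= cos_limit:
            return True
    return False


def site_hbonds(
    site: HydrationSite,
    frames: FrameSeries,
    topology: Topology,
    distance_cutoff: float = HB_DISTANCE,
    angle_cutoff_deg: float = HB_ANGLE_DEG,
) -> tuple[float, float]:
    """Mean hydrogen-bond counts (NswHB, NwwHB) per member water.

    Geometric criterion: donor–acceptor heavy-atom distance ≤ 3.5 Å and the
    donor's H–O···O angle ≤ 30°. Water–solute bonds consider solute N/O/S
    heavy atoms; the solute donates through any of its own hydrogens bonded
    within 1.25 Å of the heavy atom.
    """
    if site.n_members == 0:
        raise ValueError("site has no member observations")
    cos_limit = math.cos(math.radians(angle_cutoff_deg))
    waters = topology.water_molecules
    mol_of_water = {_molecule_id(topology, mol): w for w, mol in enumerate(waters)}
    oxygen_idx = np.array([mol[0] for mol in waters])
    hyd_idx = np.array([mol[1:] for mol in waters])  # (nw, 2)

    polar_idx = [
        a.atom_index
        for a in topology.atoms
        if a.role in (AtomRole.SOLUTE, AtomRole.LIGAND, AtomRole.ION)
        and a.element in ("N", "O", "S")
    ]
    solute_h = [
        a.atom_index
        for a in topology.atoms
        if a.role in (AtomRole.SOLUTE, AtomRole.LIGAND) and a.element == "H"
    ]

    by_frame: dict[int, list[int]] = {}
    for obs in site.member_observations:
        by_frame.setdefault(obs.frame_index, []).append(obs.molecule_id)

    nsw_vals, nww_vals = [], []
    n_waters = len(waters)
    for f, mol_ids in sorted(by_frame.items()):
        coords = frames.coordinates[f]
        box = frames.box_lengths[f]
        opos = coords[oxygen_idx]
        for mol_id in mol_ids:
            w = mol_of_water[mol_id]
            ow = opos[w]
            hw = coords[hyd_idx[w]]
            # water-water
            delta = minimum_image_displacement(opos - ow, box)
            oo = np.sqrt((delta**2).sum(axis=1))
            nww = 0
            for j in np.where((oo <= distance_cutoff) & (oo > 0))[0]:
                if _donor_aligned(ow, hw, opos[j], box, cos_limit):
                    nww += 1
                if _donor_aligned(opos[j], coords[hyd_idx[j]], ow, box, cos_limit):
                    nww += 1
            # water-solute
            nsw = 0
            for p in polar_idx:
                pp = coords[p]
                d = np.linalg.norm(minimum_image_displacement(pp - ow, box))
                if d > distance_cutoff or d == 0:
                    continue
                if _donor_aligned(ow, hw, pp, box, cos_limit):
                    nsw += 1
                hp = [
                    coords[h]
                    for h in solute_h
                    if np.linalg.norm(
                        minimum_image_displacement(coords[h] - pp, box)
                    ) <= 1.25
                ]
                if hp and _donor_aligned(pp, np.array(hp), ow, box, cos_limit):
                    nsw += 1
            nsw_vals.append(nsw)
            nww_vals.append(nww)
    return float(np.mean(nsw_vals)), float(np.mean(nww_vals))


# ---------------------------------------------------------------------------
# excess entropy (first-nearest-neighbor estimators)

def translational_excess_entropy(
    positions: np.ndarray,
    bulk_density: float,
    n_frames: Optional[int] = None,
    floor_kb: float = ENTROPY_FLOOR_KB,
    boxsize: Optional[float] = None,
) -> float:
    """Translational excess entropy in units of k_B.

    First-nearest-neighbor estimate over the pooled member-oxygen cloud,
    referenced to bulk water: with N member positions collected over
    ``n_frames`` frames, a bulk-like water presents a pooled point density
    of n_frames × ρ_bulk, which fixes the estimator's normalization so that
    bulk-like input yields 0. When ``n_frames`` is omitted each observation
    is taken to come from its own frame (fully occupied site), in which
    case the estimator converges to the differential entropy of the
    position distribution plus ln ρ_bulk.

    ``boxsize`` switches to periodic nearest-neighbor search; use it when
    the input fills a periodic box (homogeneous bulk), where a bounded
    search would inflate boundary distances. Compact site clouds do not
    need it.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least two positions")
    if n_frames is None:
        n_frames = n
    if boxsize is not None:
        positions = np.mod(positions, boxsize)
        tree = cKDTree(positions, boxsize=boxsize)
    else:
        tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    nn = d[:, 1]
    with np.errstate(divide="ignore"):
        terms = np.log(
            (n - 1) * (4.0 * math.pi / 3.0) * nn**3 * bulk_density * n_frames / n
        )
    s = EULER_GAMMA + float(np.mean(terms))
    return max(s, floor_kb)


def orientational_excess_entropy(
    quaternions: np.ndarray,
    floor_kb: float = ENTROPY_FLOOR_KB,
) -> float:
    """Orientational excess entropy in units of k_B.

    First-nearest-neighbor estimate on SO(3) with the normalized Haar
    measure: the geodesic ball of radius ω has measure (ω − sin ω)/π, so a
    uniform orientation distribution yields 0 and any concentration is
    negative.
    """
    q = np.asarray(quaternions, dtype=float)
    n = len(q)
    if n < 2:
        raise ValueError("need at least two orientations")
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    # antipodal quaternions are the same rotation: search over ±q
    doubled = np.vstack([q, -q])
    tree = cKDTree(doubled)
    # nearest other rotation: exclude self and its antipode (k=3 suffices
    # unless there are exact duplicates, handled by distance filtering)
    d, idx = tree.query(q, k=4)
    omega = np.empty(n)
    for i in range(n):
        best = None
        for dist, j in zip(d[i], idx[i]):
            if j % n == i:
                continue
            best = dist
            break
        if best is None:
            best = 0.0
        cos_half = 1.0 - best**2 / 2.0
        cos_half = min(1.0, max(-1.0, abs(cos_half)))
        omega[i] = 2.0 * math.acos(cos_half)
    with np.errstate(divide="ignore"):
        terms = np.log((n - 1) * (omega - np.sin(omega)) / math.pi)
    s = EULER_GAMMA + float(np.mean(terms))
    return max(s, floor_kb)


def site_entropy(
    site: HydrationSite,
    bulk: BulkReference,
    n_frames: Optional[int] = None,
    n_min: int = N_MIN_OBSERVATIONS,
    floor_kb: float = ENTROPY_FLOOR_KB,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(−TSᵉ_trans, −TSᵉ_orient, −TSᵉ) in kcal/mol at bulk.temperature.

    Sites with fewer than ``n_min`` member observations are flagged and get
    missing entropies.
    """
    if site.n_members < n_min:
        site.thermo.entropy_flagged = True
        return None, None, None
    positions = np.array([o.oxygen_position for o in site.member_observations])
    quats = np.array([o.orientation for o in site.member_observations])
    s_tr = translational_excess_entropy(
        positions, bulk.density, n_frames=n_frames, floor_kb=floor_kb
    )
    s_or = orientational_excess_entropy(quats, floor_kb=floor_kb)
    kT = bulk.kT
    return (-kT * s_tr, -kT * s_or, -kT * (s_tr + s_or))


# ---------------------------------------------------------------------------
# derived Table-style metrics

def derived_metrics(thermo: SiteThermo, bulk: BulkReference) -> SiteThermo:
    """Fill the derived columns from the measured ones.

    Etot = Esw + Eww; fwwHB = NwwHB/Nnbr; fenc = 1 − Nnbr/Nnbr_bulk;
    Nww_lostHB = NwwHB_bulk − NwwHB.
    """
    thermo.Etot = thermo.Esw + thermo.Eww
    thermo.fwwHB = thermo.NwwHB / thermo.Nnbr if thermo.Nnbr > 0 else 0.0
    thermo.fenc = 1.0 - thermo.Nnbr / bulk.Nnbr_bulk
    thermo.Nww_lostHB = bulk.NwwHB_bulk - thermo.NwwHB
    return thermo


def compute_site_thermo(
    site: HydrationSite,
    frames: FrameSeries,
    topology: Topology,
    bulk: BulkReference,
    model: Optional[EnergyModel] = None,
    neighbor_cutoff: float = NEIGHBOR_CUTOFF,
    n_min: int = N_MIN_OBSERVATIONS,
) -> SiteThermo:
    """Fill a site's full SiteThermo block in place."""
    esw, eww, eww_nbr, nnbr = site_energies(
        site, frames, topology, model, neighbor_cutoff
    )
    nsw, nww = site_hbonds(site, frames, topology)
    t = site.thermo
    t.Esw, t.Eww, t.Eww_nbr, t.Nnbr = esw, eww, eww_nbr, nnbr
    t.NswHB, t.NwwHB = nsw, nww
    mts_tr, mts_or, mts = site_entropy(
        site, bulk, n_frames=frames.n_frames, n_min=n_min
    )
    t.minus_TSe_trans, t.minus_TSe_orient, t.minus_TSe = mts_tr, mts_or, mts
    derived_metrics(t, bulk)
    return t
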