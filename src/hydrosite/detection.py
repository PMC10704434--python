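"""Hydration-site detection by greedy clustering of water-oxygen density.

Observations are collected for every (frame, water) whose oxygen lies in
the analysis region. Detection repeatedly seeds a 1 Å sphere at the
observation with the highest neighbor count, records a site at the local
centroid, removes the members, and stops once the best candidate's
per-frame occupancy drops below the occupancy floor (default: twice the
bulk expectation for a 1 Å sphere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import (
    AnalysisRegion,
    FrameSeries,
    HydrationSite,
    Topology,
    WaterObservation,
)

SITE_RADIUS = 1.0  # Å, fixed by the method's definition of a hydration site
DEFAULT_BULK_DENSITY = 0.0329


def default_occupancy_floor(
    bulk_density: float = DEFAULT_BULK_DENSITY, site_radius: float = SITE_RADIUS
) -> float:
    """Twice the expected bulk count in one site sphere, per frame."""
    return 2.0 * bulk_density * (4.0 / 3.0) * np.pi * site_radius**3


@dataclass
class DetectionParams:
    site_radius: float = SITE_RADIUS
    occupancy_floor: Optional[float] = None  # per-frame occupancy threshold
    min_center_separation: float = 2.0
    bulk_density: float = DEFAULT_BULK_DENSITY

    def resolved_floor(self) -> float:
        if self.occupancy_floor is not None:
            return self.occupancy_floor
        return default_occupancy_floor(self.bulk_density, self.site_radius)


def water_orientation_quaternions(
    o_pos: np.ndarray, h1_pos: np.ndarray, h2_pos: np.ndarray
) -> np.ndarray:
    """Body-frame quaternions (w, x, y, z) from the two O–H bond vectors.

    The body frame puts the H–O–H bisector on +z and the H→H axis on +x.
    """
    v1 = h1_pos - o_pos
    v2 = h2_pos - o_pos
    v1 = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
    v2 = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
    z = v1 + v2
    z = z / np.linalg.norm(z, axis=-1, keepdims=True)
    x = v1 - v2
    x = x - (x * z).sum(axis=-1, keepdims=True) * z
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    y = np.cross(z, x)
    matrices = np.stack([x, y, z], axis=-1)  # columns are body axes
    quat_xyzw = Rotation.from_matrix(matrices).as_quat()
    quat_xyzw = np.atleast_2d(quat_xyzw)
    return np.roll(quat_xyzw, 1, axis=-1)  # -> (w, x, y, z)


def collect_observations(
    frames: FrameSeries,
    topology: Topology,
    region: AnalysisRegion,
) -> list[WaterObservation]:
    """One observation per (frame, water) whose oxygen lies in the region."""
    waters = topology.water_molecules
    if not waters:
        return []
    oxygen_idx = np.array([mol[0] for mol in waters])
    h_idx = np.array([mol[1:] for mol in waters])
    mol_lookup = {tuple(mol): i for i, mol in enumerate(topology.molecules)}
    water_mol_ids = np.array([mol_lookup[tuple(mol)] for mol in waters])

    observations: list[WaterObservation] = []
    for f in range(frames.n_frames):
        coords = frames.coordinates[f]
        opos = coords[oxygen_idx]
        inside = np.where(region.contains(opos))[0]
        if len(inside) == 0:
            continue
        quats = water_orientation_quaternions(
            opos[inside], coords[h_idx[inside, 0]], coords[h_idx[inside, 1]]
        )
        for k, w in enumerate(inside):
            observations.append(
                WaterObservation(
                    frame_index=f,
                    molecule_id=int(water_mol_ids[w]),
                    oxygen_position=opos[w].copy(),
                    orientation=quats[k],
                )
            )
    return observations


def detect_sites(
    observations: Sequence[WaterObservation],
    n_frames: int,
    params: Optional[DetectionParams] = None,
) -> list[HydrationSite]:
    """Greedy density clustering into high-occupancy 1 Å spheres.

    Deterministic: candidates tie-break on (count, lowest frame index,
    lowest molecule id). Returned sites are renumbered by occupancy
    descending (site_id starts at 1).
    """
    params = params or DetectionParams()
    if not observations:
        return []
    floor_count = params.resolved_floor() * n_frames
    positions = np.array([o.oxygen_position for o in observations])
    order_key = np.array(
        [(o.frame_index, o.molecule_id) for o in observations], dtype=int
    )
    alive = np.ones(len(observations), dtype=bool)
    seed_ok = np.ones(len(observations), dtype=bool)

    sites: list[HydrationSite] = []
    accepted_centers: list[np.ndarray] = []
    while True:
        candidates = np.where(alive & seed_ok)[0]
        if len(candidates) == 0:
            break
        tree = cKDTree(positions[alive])
        alive_idx = np.where(alive)[0]
        counts_alive = np.array(
            [len(m) for m in tree.query_ball_point(positions[candidates],
                                                   params.site_radius)]
        )
        best_count = counts_alive.max()
        if best_count < floor_count:
            break
        tied = candidates[counts_alive == best_count]
        # deterministic tie-break: lowest frame index, then molecule id
        tied = tied[np.lexsort((order_key[tied, 1], order_key[tied, 0]))]
        seed = tied[0]
        members_local = tree.query_ball_point(positions[seed], params.site_radius)
        member_idx = alive_idx[members_local]
        center = positions[member_idx].mean(axis=0)
        site = HydrationSite(
            site_id=-1,
            center=center,
            fo=0.0,
            member_observations=[observations[i] for i in member_idx],
        )
        frames_hit = {observations[i].frame_index for i in member_idx}
        site.fo = min(1.0, len(frames_hit) / n_frames)
        sites.append(site)
        accepted_centers.append(center)
        alive[member_idx] = False
        near = np.linalg.norm(positions - center, axis=1) < params.min_center_separation
        seed_ok &= ~near

    sites.sort(key=lambda s: -s.fo)
    for i, site in enumerate(sites):
        site.site_id = i + 1
    return sites
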