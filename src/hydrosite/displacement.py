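"""Ligand displacement of hydration sites, crystal-water matching,
apo–holo site comparison, and solvent contributions to binding.

A site is displaced (default, envelope mode) when its center falls inside
the ligand's van der Waals envelope expanded by a 1.5 Å probe; the
center-distance mode instead tests the bare distance to the nearest ligand
heavy atom against the probe. The envelope therefore always displaces a
superset of the center-distance sites at equal probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import BulkReference, CrystalWaterSet, HydrationSite, LigandPose

DISPLACEMENT_PROBE = 1.5  # Å
MATCH_CUTOFF = 2.0  # Å: sites closer than this are the same water
LIGAND_SHELL = 5.0  # Å analysis shell around the bound pose


@dataclass
class DisplacementReport:
    displaced_flags: list[bool]
    n_displaced: int
    n_retained: int
    counts_by_category: dict
    delta_H_solv: float
    minus_T_delta_S_solv: float
    crystal_match_flags: Optional[list[bool]] = None
    crystal_match_fraction: Optional[float] = None
    notes: list[str] = field(default_factory=list)


@dataclass
class ConservedSitePair:
    apo_site_id: int
    holo_site_id: int
    center_distance: float
    delta_Etot: float
    delta_minus_TSe: Optional[float]
    delta_NswHB: float
    delta_NwwHB: float


def flag_displaced(
    sites: Sequence[HydrationSite],
    ligand: LigandPose,
    probe: float = DISPLACEMENT_PROBE,
    mode: str = "envelope",
) -> list[bool]:
    """Displacement flags for each site against a bound pose."""
    if ligand is None or ligand.n_atoms == 0:
        raise ValueError("ligand pose is empty")
    if mode not in ("envelope", "center_distance"):
        raise ValueError(f"unknown displacement mode {mode!r}")
    flags = []
    for site in sites:
        d = np.linalg.norm(ligand.heavy_atom_positions - site.center, axis=1)
        if mode == "envelope":
            displaced = bool(np.min(d - ligand.vdw_radii) <= probe)
        else:
            displaced = bool(d.min() <= probe)
        site.displaced = displaced
        flags.append(displaced)
    return flags


def match_crystal_waters(
    sites: Sequence[HydrationSite],
    crystal: CrystalWaterSet,
    ligand: LigandPose,
    match_cutoff: float = MATCH_CUTOFF,
    shell: float = LIGAND_SHELL,
) -> tuple[list[bool], float, list[str]]:
    """Greedy one-to-one matching of sites to crystallographic waters.

    Crystal waters and sites are both restricted to the ligand shell; each
    crystal water consumes at most one site, pairs taken nearest-first
    (ties by lowest indices). The fraction is matched sites over sites in
    the shell.
    """
    notes: list[str] = []
    lig = ligand.heavy_atom_positions
    site_in_shell = [
        np.linalg.norm(lig - s.center, axis=1).min() <= shell for s in sites
    ]
    if len(crystal):
        cw_in_shell = (
            np.linalg.norm(
                crystal.oxygen_positions[:, None, :] - lig[None, :, :], axis=2
            ).min(axis=1)
            <= shell
        )
        cw_positions = crystal.oxygen_positions[cw_in_shell]
    else:
        cw_positions = np.zeros((0, 3))
    flags = [False] * len(sites)
    if len(cw_positions) == 0:
        notes.append("no crystal waters in shell")
        n_shell = sum(site_in_shell)
        return flags, 0.0, notes

    pairs = []
    for si, site in enumerate(sites):
        if not site_in_shell[si]:
            continue
        d = np.linalg.norm(cw_positions - site.center, axis=1)
        for ci in range(len(cw_positions)):
            if d[ci] <= match_cutoff:
                pairs.append((d[ci], si, ci))
    used_sites: set[int] = set()
    used_waters: set[int] = set()
    for dist, si, ci in sorted(pairs, key=lambda p: (p[0], p[1], p[2])):
        if si in used_sites or ci in used_waters:
            continue
        used_sites.add(si)
        used_waters.add(ci)
        flags[si] = True
    n_shell = sum(site_in_shell)
    fraction = len(used_sites) / n_shell if n_shell else 0.0
    if n_shell == 0:
        notes.append("no sites in shell")
    return flags, fraction, notes


def binding_contributions(
    sites: Sequence[HydrationSite],
    flags: Sequence[bool],
    bulk: BulkReference,
    occupancy_weighted: bool = True,
) -> tuple[float, float, list[str]]:
    """Solvent contributions of displaced sites to binding free energy.

    delta_H_solv = Σ fo (Etot_bulk − Etot_site): positive when favorable
    water is expelled (enthalpic penalty). minus_T_delta_S_solv =
    −Σ fo (−TSᵉ_site): negative when entropy-starved water is released
    (entropic gain). Set ``occupancy_weighted=False`` for unweighted sums.
    """
    notes: list[str] = []
    delta_h = 0.0
    minus_tds = 0.0
    for site, flag in zip(sites, flags):
        if not flag:
            continue
        w = site.fo if occupancy_weighted else 1.0
        delta_h += w * (bulk.Etot_bulk - site.thermo.Etot)
        if site.thermo.minus_TSe is None:
            notes.append(f"site {site.site_id}: entropy missing, "
                         "excluded from the entropy sum")
        else:
            minus_tds += -w * site.thermo.minus_TSe
    return delta_h, minus_tds, notes


def build_report(
    sites: Sequence[HydrationSite],
    ligand: LigandPose,
    bulk: BulkReference,
    crystal: Optional[CrystalWaterSet] = None,
    probe: float = DISPLACEMENT_PROBE,
    mode: str = "envelope",
    occupancy_weighted: bool = True,
    match_cutoff: float = MATCH_CUTOFF,
    shell: float = LIGAND_SHELL,
) -> DisplacementReport:
    flags = flag_displaced(sites, ligand, probe, mode)
    delta_h, minus_tds, notes = binding_contributions(
        sites, flags, bulk, occupancy_weighted
    )
    counts: dict[str, int] = {}
    for site, flag in zip(sites, flags):
        if flag and site.labels.composite != "..":
            key = site.labels.composite
            counts[key] = counts.get(key, 0) + 1
    report = DisplacementReport(
        displaced_flags=list(flags),
        n_displaced=int(sum(flags)),
        n_retained=int(len(flags) - sum(flags)),
        counts_by_category=counts,
        delta_H_solv=delta_h,
        minus_T_delta_S_solv=minus_tds,
        notes=notes,
    )
    if crystal is not None:
        cflags, fraction, cnotes = match_crystal_waters(
            sites, crystal, ligand, match_cutoff, shell
        )
        report.crystal_match_flags = cflags
        report.crystal_match_fraction = fraction
        report.notes.extend(cnotes)
    return report


def match_apo_holo(
    apo_sites: Sequence[HydrationSite],
    holo_sites: Sequence[HydrationSite],
    match_cutoff: float = MATCH_CUTOFF,
) -> tuple[list[ConservedSitePair], list[int], list[int]]:
    """One-to-one greedy pairing of conserved sites by center distance.

    Returns (pairs, lost apo site ids, gained holo site ids). Deltas are
    holo − apo; the entropy delta is None when either side lacks it.
    """
    candidates = []
    for ai, a in enumerate(apo_sites):
        for hi, h in enumerate(holo_sites):
            d = float(np.linalg.norm(a.center - h.center))
            if d <= match_cutoff:
                candidates.append((d, ai, hi))
    used_a: set[int] = set()
    used_h: set[int] = set()
    pairs: list[ConservedSitePair] = []
    for d, ai, hi in sorted(candidates, key=lambda c: (c[0], c[1], c[2])):
        if ai in used_a or hi in used_h:
            continue
        used_a.add(ai)
        used_h.add(hi)
        a, h = apo_sites[ai], holo_sites[hi]
        if a.thermo.minus_TSe is None or h.thermo.minus_TSe is None:
            d_mts = None
        else:
            d_mts = h.thermo.minus_TSe - a.thermo.minus_TSe
        pairs.append(
            ConservedSitePair(
                apo_site_id=a.site_id,
                holo_site_id=h.site_id,
                center_distance=d,
                delta_Etot=h.thermo.Etot - a.thermo.Etot,
                delta_minus_TSe=d_mts,
                delta_NswHB=h.thermo.NswHB - a.thermo.NswHB,
                delta_NwwHB=h.thermo.NwwHB - a.thermo.NwwHB,
            )
        )
    lost = [a.site_id for i, a in enumerate(apo_sites) if i not in used_a]
    gained = [h.site_id for i, h in enumerate(holo_sites) if i not in used_h]
    return pairs, lost, gained
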