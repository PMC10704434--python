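"""Site classification into environment (A/P/C), water-structure (En/Fr)
and energetic (F/U) labels, plus Table-style category summaries.

Environment looks at pocket heavy atoms within 3.5 Å of the site center
with priority charged > polar > apolar. The water-structure label compares
the per-first-shell-neighbor water–water energy against bulk (the reading
under which all published category rows are self-consistent); comparing
total Eww instead remains available via ``ww_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AtomRole,
    BulkReference,
    HydrationSite,
    SiteThermo,
    Topology,
)

ENV_CUTOFF = 3.5  # Å first-shell contact distance
EXPOSED_CUTOFF = 6.0  # Å: no pocket atom this close -> solvent-exposed site

# side-chain atoms belonging to formally charged groups at physiological pH
CHARGED_GROUP_ATOMS = {
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
    "LYS": {"NZ"},
    "ARG": {"CZ", "NE", "NH1", "NH2"},
    "HIP": {"ND1", "NE2", "CE1"},
}
POLAR_SIDECHAIN_RESIDUES = {
    "SER", "THR", "ASN", "GLN", "TYR", "HIS", "HID", "HIE", "CYS", "TRP",
}
CHARGED_PARTIAL_CHARGE = 0.9  # |q| >= this marks a charged pseudo-atom
POLAR_PARTIAL_CHARGE = 0.3  # |q| >= this marks a polar pseudo-atom


def _atom_env_class(atom) -> str:
    if atom.role is AtomRole.ION:
        return "C"
    if abs(atom.charge) >= CHARGED_PARTIAL_CHARGE:
        return "C"
    group = CHARGED_GROUP_ATOMS.get(atom.residue_name)
    if group and atom.name in group:
        return "C"
    if atom.element in ("N", "O", "S"):
        return "P"
    if abs(atom.charge) >= POLAR_PARTIAL_CHARGE:
        return "P"
    return "A"


def classify_environment(
    site: HydrationSite,
    topology: Topology,
    env_cutoff: float = ENV_CUTOFF,
    exposed_cutoff: float = EXPOSED_CUTOFF,
) -> str:
    """Assign A/P/C from pocket heavy atoms near the site center."""
    ref = topology.solute_reference_coordinates
    if ref is None:
        raise ValueError("topology carries no solute reference coordinates")
    # reference coordinates are stored for solute/ion/ligand atoms in order
    all_ref_atoms = [
        a
        for a in topology.atoms
        if a.role in (AtomRole.SOLUTE, AtomRole.ION, AtomRole.LIGAND)
    ]
    pocket_atoms = [a for a in all_ref_atoms if a.element != "H"]
    positions = np.array(
        [ref[i] for i, a in enumerate(all_ref_atoms) if a.element != "H"]
    )
    if len(positions) == 0:
        site.labels.exposed = True
        return "A"
    d = np.linalg.norm(positions - site.center, axis=1)
    if d.min() > exposed_cutoff:
        site.labels.exposed = True
        return "A"
    near = [a for a, dist in zip(pocket_atoms, d) if dist <= env_cutoff]
    classes = {_atom_env_class(a) for a in near}
    if "C" in classes:
        return "C"
    if "P" in classes:
        return "P"
    return "A"


def classify_energetics(
    thermo: SiteThermo,
    bulk: BulkReference,
    ww_mode: str = "per_neighbor",
) -> tuple[str, str]:
    """(ww_class, tot_class): En/Fr and F/U against the bulk reference.

    F requires strictly lower total energy than bulk (ties are
    unfavorable); En admits ties (they have measure zero on real data).
    """
    tot_class = "F" if thermo.Etot < bulk.Etot_bulk else "U"
    if ww_mode == "per_neighbor":
        ww_class = "En" if thermo.Eww_nbr <= bulk.Eww_nbr_bulk else "Fr"
    elif ww_mode == "total":
        ww_class = "En" if thermo.Eww <= bulk.Etot_bulk else "Fr"
    else:
        raise ValueError(f"unknown ww_mode {ww_mode!r}")
    return ww_class, tot_class


def classify_sites(
    sites: Sequence[HydrationSite],
    topology: Topology,
    bulk: BulkReference,
    ww_mode: str = "per_neighbor",
) -> None:
    for site in sites:
        site.labels.env_class = classify_environment(site, topology)
        ww, tot = classify_energetics(site.thermo, bulk, ww_mode)
        site.labels.ww_class = ww
        site.labels.tot_class = tot


THERMO_COLUMNS = [
    "fo", "Esw", "Eww", "Etot", "Eww_nbr", "minus_TSe_trans",
    "minus_TSe_orient", "minus_TSe", "Nnbr", "fenc", "NswHB", "NwwHB",
    "fwwHB", "Nww_lostHB",
]


@dataclass
class CategorySummary:
    table: pd.DataFrame  # one row per composite category (+ pooled rows)
    env_fractions: dict = field(default_factory=dict)
    total: int = 0


def _site_row(site: HydrationSite) -> dict:
    t = site.thermo
    row = {"fo": site.fo}
    for col in THERMO_COLUMNS[1:]:
        row[col] = getattr(t, col)
    return row


def summarize_categories(sites: Sequence[HydrationSite]) -> CategorySummary:
    """Per-composite-category counts and unweighted column means.

    Adds pooled displaced/undisplaced rows when displacement flags are set.
    """
    records = []
    for site in sites:
        row = _site_row(site)
        row["category"] = site.labels.composite
        row["env"] = site.labels.env_class
        row["displaced"] = site.displaced
        records.append(row)
    df = pd.DataFrame(records)
    rows = []
    for cat, group in df.groupby("category"):
        entry = {"type": cat, "count": len(group)}
        entry.update(group[THERMO_COLUMNS].mean().to_dict())
        rows.append(entry)
    if df["displaced"].notna().any():
        for label, mask in (
            ("Undisplaced", df["displaced"] == False),  # noqa: E712
            ("Displaced", df["displaced"] == True),  # noqa: E712
        ):
            group = df[mask]
            if len(group):
                entry = {"type": label, "count": len(group)}
                entry.update(group[THERMO_COLUMNS].mean().to_dict())
                rows.append(entry)
    table = pd.DataFrame(rows)
    total = len(sites)
    env_fractions = {
        env: 100.0 * (df["env"] == env).sum() / total for env in ("A", "P", "C")
    }
    return CategorySummary(table=table, env_fractions=env_fractions, total=total)


def environment_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Percent of sites per environment class from raw counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sites to summarize")
    return {k: 100.0 * v / total for k, v in counts.items()}
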