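"""Shared fixtures: synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hydrosite import (
    AnalysisRegion,
    BulkReference,
    SiteSpec,
    analyze,
    generate_ligand_and_crystal,
    generate_pocket_system,
)
from hydrosite.pipeline import THREE_SITE_SCENARIO, scenario_site_specs


@pytest.fixture(scope="session")
def bulk() -> BulkReference:
    return BulkReference()


@pytest.fixture(scope="session")
def single_site_system():
    """One fully occupied charged site, tight spread, tiny system."""
    specs = [
        SiteSpec(center=[0.0, 0.0, 0.0], occupancy_target=1.0,
                 positional_sigma=0.15, nearest_residue_class="charged")
    ]
    topology, frames, truth = generate_pocket_system(
        specs, n_frames=100, n_background_waters=25, seed=101,
        n_scaffold_atoms=0,
    )
    return specs, topology, frames, truth


@pytest.fixture(scope="session")
def three_site_run(bulk):
    """The bundled three-site pocket scenario, fully analyzed in memory.

    2000 frames; sites of charged/polar/apolar character with occupancies
    0.9/0.7/0.5 and spreads 0.20/0.25/0.30 Å; ligand displacing sites
    {0, 2}; crystal waters at sites {0, 1} plus one decoy.
    """
    scenario = THREE_SITE_SCENARIO
    specs = scenario_site_specs(scenario)
    topology, frames, truth = generate_pocket_system(
        specs,
        n_frames=scenario["n_frames"],
        n_background_waters=scenario["n_background_waters"],
        seed=2026,
    )
    region = AnalysisRegion(
        mode="sphere",
        sphere_center=scenario["region"]["sphere_center"],
        sphere_radius=scenario["region"]["sphere_radius"],
    )
    sites = analyze(topology, frames, region, bulk)
    pose, crystal = generate_ligand_and_crystal(
        specs,
        displace_subset=scenario["displace_subset"],
        crystal_site_indices=scenario["crystal_sites"],
        n_decoys=scenario["n_decoys"],
        seed=2027,
    )
    return {
        "scenario": scenario,
        "specs": specs,
        "topology": topology,
        "frames": frames,
        "truth": truth,
        "region": region,
        "sites": sites,
        "ligand": pose,
        "crystal": crystal,
    }


def site_by_planted_center(sites, center, tol=1.0):
    center = np.asarray(center, dtype=float)
    for site in sites:
        if np.linalg.norm(site.center - center) <= tol:
            return site
    raise AssertionError(f"no detected site near planted center {center}")
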