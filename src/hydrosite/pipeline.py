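"""One-command orchestration: config validation, stage execution, manifest.

A run executes collect → detect → thermo → classify and then, as
configured, displacement/crystal matching, apo–holo comparison and the
solvation landscape, writing a site table, category summary, displacement
report and a manifest that records every resolved default. Identical
config + seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .core import (
    AnalysisRegion,
    BulkReference,
    EnergyModel,
    FrameSeries,
    Topology,
)
from .detection import DetectionParams, collect_observations, detect_sites
from .displacement import build_report
from .landscape import count_shell_waters, free_energy_landscape
from .synthetic import (
    SiteSpec,
    generate_ligand_and_crystal,
    generate_pocket_system,
)
from .thermo import compute_site_thermo
from .classification import classify_sites, summarize_categories
from . import io as hio


class RegionConfig(BaseModel):
    mode: str = "sphere"
    shell_distance: float = 5.0
    sphere_center: Optional[list[float]] = None
    sphere_radius: float = 8.0


class DetectionConfig(BaseModel):
    site_radius: float = 1.0
    occupancy_floor: Optional[float] = None
    min_center_separation: float = 2.0
    bulk_density: float = 0.0329


class EnergyConfig(BaseModel):
    cutoff: float = 10.0
    minimum_image: bool = True


class BulkConfig(BaseModel):
    Etot_bulk: float = -9.53
    Eww_nbr_bulk: float = -1.36
    Nnbr_bulk: float = 5.26
    NwwHB_bulk: float = 3.33
    fwwHB_bulk: float = 0.63
    density: float = 0.0329
    temperature: float = 300.0


class DisplacementConfig(BaseModel):
    probe: float = 1.5
    mode: str = "envelope"
    occupancy_weighted: bool = True
    match_cutoff: float = 2.0
    shell: float = 5.0


class LandscapeConfig(BaseModel):
    coordinate_tsv: Optional[str] = None
    bins_x: int = 60
    shell: float = 5.0
    ligand_residue: str = "LIG"


class RunConfig(BaseModel):
    topology: str
    parameters: str
    trajectory: str
    dialect: str = "multi_model_pdb"
    ligand: Optional[str] = None
    crystal_waters: Optional[str] = None
    region: RegionConfig = Field(default_factory=RegionConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    energy: EnergyConfig = Field(default_factory=EnergyConfig)
    bulk: BulkConfig = Field(default_factory=BulkConfig)
    displacement: DisplacementConfig = Field(default_factory=DisplacementConfig)
    landscape: LandscapeConfig = Field(default_factory=LandscapeConfig)
    ww_mode: str = "per_neighbor"
    seed: int = 0
    output_dir: str = "hsa_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _bulk_reference(cfg: BulkConfig) -> BulkReference:
    return BulkReference(**cfg.model_dump())


def _region(cfg: RegionConfig, ligand) -> AnalysisRegion:
    if cfg.mode == "ligand_shell":
        return AnalysisRegion(
            mode="ligand_shell", ligand=ligand, shell_distance=cfg.shell_distance
        )
    return AnalysisRegion(
        mode="sphere",
        sphere_center=np.asarray(cfg.sphere_center, dtype=float),
        sphere_radius=cfg.sphere_radius,
    )


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze(
    topology: Topology,
    frames: FrameSeries,
    region: AnalysisRegion,
    bulk: BulkReference,
    detection: Optional[DetectionParams] = None,
    model: Optional[EnergyModel] = None,
    ww_mode: str = "per_neighbor",
):
    """Library-level collect → detect → thermo → classify."""
    observations = collect_observations(frames, topology, region)
    sites = detect_sites(observations, frames.n_frames, detection)
    model = model or EnergyModel()
    for site in sites:
        compute_site_thermo(site, frames, topology, bulk, model)
    classify_sites(sites, topology, bulk, ww_mode)
    return sites


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    topology = hio.read_topology(config.topology, config.parameters)
    frames = hio.read_trajectory(config.trajectory, topology, config.dialect)
    ligand = hio.read_ligand_pose(config.ligand) if config.ligand else None
    crystal = (
        hio.read_crystal_waters(config.crystal_waters)
        if config.crystal_waters
        else None
    )
    bulk = _bulk_reference(config.bulk)
    region = _region(config.region, ligand)
    model = EnergyModel(
        cutoff=config.energy.cutoff, minimum_image=config.energy.minimum_image
    )
    detection = DetectionParams(
        site_radius=config.detection.site_radius,
        occupancy_floor=config.detection.occupancy_floor,
        min_center_separation=config.detection.min_center_separation,
        bulk_density=config.detection.bulk_density,
    )

    sites = analyze(topology, frames, region, bulk, detection, model,
                    config.ww_mode)

    artifacts: dict[str, str] = {}
    notes: list[str] = []

    report = None
    if ligand is not None and sites:
        report = build_report(
            sites, ligand, bulk, crystal,
            probe=config.displacement.probe,
            mode=config.displacement.mode,
            occupancy_weighted=config.displacement.occupancy_weighted,
            match_cutoff=config.displacement.match_cutoff,
            shell=config.displacement.shell,
        )

    if sites:
        site_table = out / "site_table.tsv"
        hio.write_site_table(sites, site_table)
        artifacts["site_table"] = str(site_table)
        summary = summarize_categories(sites)
        cat_path = out / "category_summary.tsv"
        summary.table.to_csv(cat_path, sep="\t", index=False,
                             float_format="%.4f")
        artifacts["category_summary"] = str(cat_path)
        frac_path = out / "environment_fractions.json"
        with open(frac_path, "w") as fh:
            json.dump(summary.env_fractions, fh, indent=1)
        artifacts["environment_fractions"] = str(frac_path)
    else:
        notes.append("no hydration sites above the occupancy floor")

    if report is not None:
        rep_path = out / "displacement_report.json"
        with open(rep_path, "w") as fh:
            json.dump(
                {
                    "n_displaced": report.n_displaced,
                    "n_retained": report.n_retained,
                    "displaced_flags": report.displaced_flags,
                    "counts_by_category": report.counts_by_category,
                    "delta_H_solv": report.delta_H_solv,
                    "minus_T_delta_S_solv": report.minus_T_delta_S_solv,
                    "crystal_match_flags": report.crystal_match_flags,
                    "crystal_match_fraction": report.crystal_match_fraction,
                    "notes": report.notes,
                },
                fh,
                indent=1,
            )
        artifacts["displacement_report"] = str(rep_path)

    if config.landscape.coordinate_tsv:
        lig_atoms = [
            a.atom_index
            for a in topology.atoms
            if a.residue_name == config.landscape.ligand_residue
        ]
        if not lig_atoms:
            notes.append(
                "landscape skipped: no ligand atoms in the trajectory topology"
            )
        else:
            coord = hio.read_frame_series_tsv(config.landscape.coordinate_tsv)
            y = count_shell_waters(frames, topology, lig_atoms,
                                   config.landscape.shell)
            x = coord["x"].to_numpy()
            weights = (
                coord["weight"].to_numpy() if "weight" in coord.columns else None
            )
            if weights is None:
                notes.append("landscape uses raw frame counts (no weights)")
            grid = free_energy_landscape(
                x, y[coord["frame_index"].to_numpy(dtype=int)],
                weights=weights,
                temperature=bulk.temperature,
            )
            fes_path = out / "landscape.tsv"
            fes = pd.DataFrame(grid.free_energy.filled(np.nan))
            fes.to_csv(fes_path, sep="\t", index=False, header=False,
                       float_format="%.6f")
            artifacts["landscape"] = str(fes_path)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": config.model_dump(),
        "resolved": {
            "occupancy_floor": detection.resolved_floor(),
            "bulk_reference": bulk.__dict__,
            "n_frames": frames.n_frames,
            "n_sites": len(sites),
        },
        "artifact_checksums": {
            k: _file_checksum(Path(v)) for k, v in artifacts.items()
        },
        "notes": notes,
    }
    man_path = out / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    artifacts["manifest"] = str(man_path)
    return artifacts


# ---------------------------------------------------------------------------
# synthetic scenarios

THREE_SITE_SCENARIO = {
    "name": "three-site pocket",
    "n_frames": 2000,
    "n_background_waters": 120,
    "bulk_density": 0.0329,
    "dialect": "multi_model_pdb",
    "sites": [
        {"center": [0.0, 0.0, 0.0], "occupancy": 0.9, "sigma": 0.20,
         "orientation": "vmf", "kappa": 20.0, "residue_class": "charged"},
        {"center": [4.6, 0.0, 0.0], "occupancy": 0.7, "sigma": 0.25,
         "orientation": "uniform", "residue_class": "polar"},
        {"center": [2.3, 3.983, 0.0], "occupancy": 0.5, "sigma": 0.30,
         "orientation": "uniform", "residue_class": "apolar"},
    ],
    "displace_subset": [0, 2],
    "crystal_sites": [0, 1],
    "n_decoys": 1,
    "region": {
        "mode": "sphere",
        "sphere_center": [2.3, 1.328, 0.0],
        "sphere_radius": 4.5,
    },
}


def scenario_site_specs(scenario: dict) -> list[SiteSpec]:
    specs = []
    for s in scenario["sites"]:
        specs.append(
            SiteSpec(
                center=np.asarray(s["center"], dtype=float),
                occupancy_target=float(s.get("occupancy", 1.0)),
                positional_sigma=float(s.get("sigma", 0.2)),
                orientation_mode=s.get("orientation", "uniform"),
                vmf_kappa=float(s.get("kappa", 10.0)),
                nearest_residue_class=s.get("residue_class", "apolar"),
            )
        )
    return specs


def run_synthetic(
    scenario: dict | str | Path,
    seed: int,
    output_dir: str | Path,
) -> dict:
    """Generate a scenario's input files plus its ground-truth JSON."""
    if not isinstance(scenario, dict):
        with open(scenario) as fh:
            scenario = yaml.safe_load(fh)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = scenario_site_specs(scenario)
    topology, frames, truth = generate_pocket_system(
        specs,
        n_frames=int(scenario["n_frames"]),
        n_background_waters=int(scenario["n_background_waters"]),
        seed=seed,
        bulk_density=float(scenario.get("bulk_density", 0.0329)),
    )
    dialect = scenario.get("dialect", "multi_model_pdb")
    suffix = {"multi_model_pdb": "pdb", "dcd": "dcd", "xtc": "xtc"}[dialect]

    top_path = out / "topology.pdb"
    hio.write_topology_pdb(
        topology, frames.coordinates[0], top_path, frames.box_lengths[0]
    )
    params_path = out / "parameters.json"
    hio.write_parameters_json(topology, params_path)
    traj_path = out / f"trajectory.{suffix}"
    hio.write_trajectory(frames, topology, traj_path, dialect)

    pose, crystal = generate_ligand_and_crystal(
        specs,
        displace_subset=scenario.get("displace_subset", []),
        probe=float(scenario.get("probe", 1.5)),
        crystal_site_indices=scenario.get("crystal_sites"),
        n_decoys=int(scenario.get("n_decoys", 0)),
        seed=seed + 1,
    )
    ligand_path = out / "ligand.pdb"
    hio.write_ligand_pose(pose, ligand_path)
    crystal_path = out / "crystal_waters.pdb"
    hio.write_crystal_waters(crystal, crystal_path)

    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "seed": seed,
                "n_sites": len(specs),
                "centers": [list(map(float, s.center)) for s in specs],
                "occupancy_targets": [s.occupancy_target for s in specs],
                "positional_sigmas": [s.positional_sigma for s in specs],
                "residue_classes": [s.nearest_residue_class for s in specs],
                "empirical_occupancies": truth.planted_occupancies().tolist(),
                "displace_subset": scenario.get("displace_subset", []),
                "crystal_sites": scenario.get("crystal_sites", []),
                "box_lengths": truth.box_lengths.tolist(),
            },
            fh,
            indent=1,
        )

    config = RunConfig(
        topology=str(top_path),
        parameters=str(params_path),
        trajectory=str(traj_path),
        dialect=dialect,
        ligand=str(ligand_path),
        crystal_waters=str(crystal_path),
        region=RegionConfig(**scenario.get("region", {})),
        detection=DetectionConfig(
            bulk_density=float(scenario.get("bulk_density", 0.0329))
        ),
        seed=seed,
        output_dir=str(out / "analysis"),
    )
    config_path = out / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)

    return {
        "topology": str(top_path),
        "parameters": str(params_path),
        "trajectory": str(traj_path),
        "ligand": str(ligand_path),
        "crystal_waters": str(crystal_path),
        "ground_truth": str(truth_path),
        "config": str(config_path),
    }
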