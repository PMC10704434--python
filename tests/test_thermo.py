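"""Energetics, hydrogen bonds, entropy estimators, and derived metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hydrosite import (
    AnalysisRegion,
    AtomRecord,
    AtomRole,
    BulkReference,
    EnergyModel,
    FrameSeries,
    HydrationSite,
    SiteThermo,
    Topology,
    WaterObservation,
    collect_observations,
    derived_metrics,
    detect_sites,
    pair_energy,
    site_energies,
    site_entropy,
    site_hbonds,
)
from hydrosite.detection import DetectionParams
from hydrosite.synthetic import (
    TIP3P_EPS_O,
    TIP3P_Q_O,
    TIP3P_SIGMA_O,
    random_unit_quaternions,
    sample_vmf_quaternions,
    water_coordinates,
)
from hydrosite.thermo import (
    orientational_excess_entropy,
    translational_excess_entropy,
)


def _atom(idx, charge=0.0, sigma=0.0, eps=0.0, element="O", role=AtomRole.SOLUTE):
    return AtomRecord(idx, "X", element, "RES", 0, "0", role, charge, sigma, eps)


# ---------------------------------------------------------------------------
# pair energy

def test_pair_energy_zero_parameters():
    a, b = _atom(0), _atom(1)
    for r in (0.5, 1.0, 5.0):
        assert pair_energy(a, b, r) == 0.0


def test_pair_energy_lj_root_at_sigma():
    a = _atom(0, sigma=3.0, eps=0.2)
    b = _atom(1, sigma=3.0, eps=0.2)
    assert pair_energy(a, b, 3.0) == pytest.approx(0.0, abs=1e-12)


def test_pair_energy_tip3p_oxygens_hand_value():
    a = _atom(0, TIP3P_Q_O, TIP3P_SIGMA_O, TIP3P_EPS_O)
    b = _atom(1, TIP3P_Q_O, TIP3P_SIGMA_O, TIP3P_EPS_O)
    r = 2.8
    coulomb = 332.0636 * TIP3P_Q_O**2 / r
    sr6 = (TIP3P_SIGMA_O / r) ** 6
    lj = 4 * TIP3P_EPS_O * (sr6**2 - sr6)
    assert pair_energy(a, b, r) == pytest.approx(coulomb + lj, abs=1e-12)


def test_pair_energy_cutoff_and_zero_distance():
    a = _atom(0, charge=1.0)
    b = _atom(1, charge=1.0)
    assert pair_energy(a, b, 10.1) == 0.0
    with pytest.raises(ValueError):
        pair_energy(a, b, 0.0)


# ---------------------------------------------------------------------------
# site energies

def _water_topology(n_waters):
    atoms, molecules = [], []
    for w in range(n_waters):
        base = 3 * w
        atoms.append(_atom(base, TIP3P_Q_O, TIP3P_SIGMA_O, TIP3P_EPS_O,
                           "O", AtomRole.WATER_OXYGEN))
        atoms.append(_atom(base + 1, -TIP3P_Q_O / 2, 0, 0, "H",
                           AtomRole.WATER_HYDROGEN))
        atoms.append(_atom(base + 2, -TIP3P_Q_O / 2, 0, 0, "H",
                           AtomRole.WATER_HYDROGEN))
        molecules.append([base, base + 1, base + 2])
    return Topology(atoms=atoms, molecules=molecules)


def _observation(frame, mol_id, position):
    return WaterObservation(frame, mol_id, np.asarray(position, float),
                            np.array([1.0, 0.0, 0.0, 0.0]))


def test_isolated_water_has_no_water_energy():
    top = _water_topology(1)
    coords = water_coordinates(np.array([5.0, 5.0, 5.0]),
                               np.array([1.0, 0, 0, 0]))
    frames = FrameSeries(coords[None], np.array([50.0, 50.0, 50.0]))
    site = HydrationSite(1, np.array([5.0, 5.0, 5.0]), 1.0,
                         [_observation(0, 0, [5.0, 5.0, 5.0])])
    esw, eww, eww_nbr, nnbr = site_energies(site, frames, top)
    assert esw == 0.0 and eww == 0.0 and nnbr == 0.0
    assert eww_nbr == 0.0 and not site.thermo.eww_nbr_defined


def test_water_dimer_half_convention():
    """Each water of a dimer is assigned half the full pair energy."""
    top = _water_topology(2)
    q = np.array([1.0, 0, 0, 0])
    c1 = water_coordinates(np.array([5.0, 5.0, 5.0]), q)
    c2 = water_coordinates(np.array([7.8, 5.0, 5.0]), q)
    coords = np.vstack([c1, c2])
    frames = FrameSeries(coords[None], np.array([50.0, 50.0, 50.0]))
    model = EnergyModel()
    full = 0.0
    for i in range(3):
        for j in range(3, 6):
            r = np.linalg.norm(coords[i] - coords[j])
            full += pair_energy(top.atoms[i], top.atoms[j], r, model)
    site = HydrationSite(1, c1[0], 1.0, [_observation(0, 0, c1[0])])
    _, eww, eww_nbr, nnbr = site_energies(site, frames, top, model)
    assert eww == pytest.approx(0.5 * full, abs=1e-10)
    assert nnbr == 1.0
    assert eww_nbr == pytest.approx(0.5 * full, abs=1e-10)


def test_site_energies_match_brute_force_oracle(single_site_system, bulk):
    """Vectorized energies equal the scalar double-loop oracle to 1e-8."""
    from hydrosite.synthetic import brute_force_water_energies

    _, topology, frames, _ = single_site_system
    region = AnalysisRegion(mode="sphere", sphere_center=[0, 0, 0],
                            sphere_radius=2.0)
    obs = collect_observations(frames, topology, region)
    site = detect_sites(obs, frames.n_frames, DetectionParams())[0]
    model = EnergyModel()
    esw, eww, _, _ = site_energies(site, frames, topology, model)

    waters = topology.water_molecules
    mol_lookup = {tuple(m): i for i, m in enumerate(topology.molecules)}
    water_of_mol = {mol_lookup[tuple(m)]: w for w, m in enumerate(waters)}
    esw_oracle, eww_oracle = [], []
    for o in site.member_observations[:25]:
        bf_esw, bf_eww = brute_force_water_energies(
            topology, frames.coordinates[o.frame_index],
            frames.box_lengths[o.frame_index], model,
        )
        w = water_of_mol[o.molecule_id]
        esw_oracle.append(bf_esw[w])
        eww_oracle.append(bf_eww[w])
    # oracle restricted to the first 25 members: recompute the mean there
    esw25, eww25, _, _ = site_energies(
        HydrationSite(1, site.center, site.fo, site.member_observations[:25]),
        frames, topology, model,
    )
    assert esw25 == pytest.approx(np.mean(esw_oracle), abs=1e-8)
    assert eww25 == pytest.approx(np.mean(eww_oracle), abs=1e-8)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _aligned_dimer(distance, angle_deg):
    """Two waters; donor H of the first rotated off the O–O axis."""
    q = np.array([1.0, 0, 0, 0])
    c2 = water_coordinates(np.array([distance, 0.0, 0.0]), q)
    # first water: put one O–H bond at angle_deg from the O–O axis
    theta = math.radians(angle_deg)
    h1 = 0.9572 * np.array([math.cos(theta), math.sin(theta), 0.0])
    h2 = 0.9572 * np.array([-0.3, -0.9, 0.0])
    h2 = 0.9572 * h2 / np.linalg.norm(h2)
    c1 = np.vstack([np.zeros(3), h1, h2])
    return np.vstack([c1, c2])


@pytest.mark.parametrize(
    "distance,angle,expected",
    [
        (2.8, 10.0, 1.0),  # close and aligned: one bond for each water
        (2.8, 45.0, 0.0),  # misaligned donor
        (3.6, 5.0, 0.0),  # distance criterion fails
    ],
)
def test_water_water_hbond_geometry(distance, angle, expected):
    top = _water_topology(2)
    coords = _aligned_dimer(distance, angle)
    frames = FrameSeries(coords[None], np.array([60.0, 60.0, 60.0]))
    for mol_id in (0, 1):
        site = HydrationSite(
            1, coords[3 * mol_id], 1.0,
            [_observation(0, mol_id, coords[3 * mol_id])],
        )
        _, nww = site_hbonds(site, frames, top)
        assert nww == expected


def test_isolated_water_has_no_hbonds():
    top = _water_topology(1)
    coords = water_coordinates(np.zeros(3), np.array([1.0, 0, 0, 0]))
    frames = FrameSeries(coords[None], np.array([60.0, 60.0, 60.0]))
    site = HydrationSite(1, np.zeros(3), 1.0, [_observation(0, 0, np.zeros(3))])
    assert site_hbonds(site, frames, top) == (0.0, 0.0)


def test_water_donates_to_solute_acceptor():
    top = _water_topology(1)
    top.atoms.append(_atom(3, charge=0.0, element="O", role=AtomRole.SOLUTE))
    top.molecules.append([3])
    top = Topology(atoms=top.atoms, molecules=top.molecules)
    q = np.array([1.0, 0, 0, 0])
    w = water_coordinates(np.zeros(3), q)
    # acceptor placed along one O–H bond direction at 2.9 Å
    direction = (w[1] - w[0]) / np.linalg.norm(w[1] - w[0])
    coords = np.vstack([w, 2.9 * direction])
    frames = FrameSeries(coords[None], np.array([60.0, 60.0, 60.0]))
    site = HydrationSite(1, np.zeros(3), 1.0, [_observation(0, 0, np.zeros(3))])
    nsw, nww = site_hbonds(site, frames, top)
    assert nsw == 1.0 and nww == 0.0


# ---------------------------------------------------------------------------
# entropy estimators

RHO_BULK = 0.0329


def test_translational_entropy_uniform_bulk_calibration():
    """Bulk-like input (pooled density n_frames × ρ) gives 0 ± 0.05 k_B."""
    rng = np.random.default_rng(42)
    n = 10_000
    edge = 10.0
    n_frames = int(round(n / (RHO_BULK * edge**3)))
    positions = rng.uniform(0, edge, size=(n, 3))
    s = translational_excess_entropy(
        positions, RHO_BULK, n_frames=n_frames, boxsize=edge
    )
    assert abs(s) < 0.05


@pytest.mark.parametrize("sigma", [0.2, 0.3, 0.5])
def test_translational_entropy_gaussian_closed_form(sigma):
    rng = np.random.default_rng(7)
    positions = sigma * rng.standard_normal((10_000, 3))
    s = translational_excess_entropy(positions, RHO_BULK)
    closed = 1.5 * math.log(2 * math.pi * math.e * sigma**2) + math.log(RHO_BULK)
    assert s == pytest.approx(closed, rel=0.05)


def test_translational_entropy_monotone_in_concentration():
    rng = np.random.default_rng(11)
    values = []
    for sigma in (0.5, 0.3, 0.2, 0.1):
        pos = sigma * rng.standard_normal((4000, 3))
        values.append(translational_excess_entropy(pos, RHO_BULK))
    assert values == sorted(values, reverse=True)


def test_orientational_entropy_uniform_is_zero():
    rng = np.random.default_rng(13)
    q = random_unit_quaternions(10_000, rng)
    assert abs(orientational_excess_entropy(q)) < 0.05


def test_orientational_entropy_monotone_in_kappa():
    rng = np.random.default_rng(17)
    mu = np.array([1.0, 0, 0, 0])
    values = []
    for kappa in (2.0, 10.0, 50.0):
        q = sample_vmf_quaternions(3000, mu, kappa, rng)
        values.append(orientational_excess_entropy(q))
    assert values == sorted(values, reverse=True)


def test_identical_orientations_clipped_at_floor():
    q = np.tile(np.array([1.0, 0, 0, 0]), (100, 1))
    assert orientational_excess_entropy(q) == -10.0


def test_planted_sigma_recovered_from_entropy():
    """Inverting the Gaussian closed form recovers σ within 10%."""
    rng = np.random.default_rng(23)
    sigma = 0.25
    pos = sigma * rng.standard_normal((10_000, 3))
    s = translational_excess_entropy(pos, RHO_BULK)
    sigma_hat = math.sqrt(
        math.exp((s - math.log(RHO_BULK)) / 1.5) / (2 * math.pi * math.e)
    )
    assert sigma_hat == pytest.approx(sigma, rel=0.10)


def test_site_entropy_requires_minimum_observations(bulk):
    site = HydrationSite(
        1, np.zeros(3), 0.1,
        [_observation(f, 0, [0.01 * f, 0, 0]) for f in range(10)],
    )
    result = site_entropy(site, bulk, n_frames=100)
    assert result == (None, None, None)
    assert site.thermo.entropy_flagged


def test_site_entropy_units_and_sign(bulk):
    rng = np.random.default_rng(29)
    members = [
        WaterObservation(f, 0, 0.2 * rng.standard_normal(3),
                         random_unit_quaternions(1, rng)[0])
        for f in range(400)
    ]
    site = HydrationSite(1, np.zeros(3), 1.0, members)
    mts_tr, mts_or, mts = site_entropy(site, bulk, n_frames=400)
    assert mts == pytest.approx(mts_tr + mts_or, abs=1e-12)
    # a tightly localized water pays a positive free-energy penalty
    assert mts_tr > 0
    kT = 0.0019872041 * 300.0
    closed = 1.5 * math.log(2 * math.pi * math.e * 0.04) + math.log(bulk.density)
    assert mts_tr == pytest.approx(-kT * closed, rel=0.15)


# ---------------------------------------------------------------------------
# derived metrics

def test_derived_metrics_bulk_row_identities(bulk):
    t = SiteThermo(Esw=0.0, Eww=-9.53, Nnbr=5.26, NwwHB=3.33)
    derived_metrics(t, bulk)
    assert t.Etot == pytest.approx(-9.53)
    assert t.fwwHB == pytest.approx(0.63, abs=0.005)
    assert t.fenc == pytest.approx(0.0, abs=1e-12)
    assert t.Nww_lostHB == pytest.approx(0.0, abs=1e-12)


def test_derived_metrics_published_rows(bulk):
    t = SiteThermo(Nnbr=2.64)
    derived_metrics(t, bulk)
    assert t.fenc == pytest.approx(0.50, abs=0.005)
    t = SiteThermo(NwwHB=1.55)
    derived_metrics(t, bulk)
    assert t.Nww_lostHB == pytest.approx(1.78, abs=1e-9)


def test_derived_metrics_zero_neighbors(bulk):
    t = SiteThermo(Esw=-1.0, Eww=0.0, Nnbr=0.0, NwwHB=0.0)
    derived_metrics(t, bulk)
    assert t.fwwHB == 0.0
    assert t.fenc == pytest.approx(1.0)
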