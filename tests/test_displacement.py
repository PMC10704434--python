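"""Displacement flags, crystal matching, binding contributions, apo–holo."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrosite import (
    BulkReference,
    CrystalWaterSet,
    HydrationSite,
    LigandPose,
    WaterObservation,
    binding_contributions,
    flag_displaced,
    match_apo_holo,
    match_crystal_waters,
    site_entropy,
)


def _site(sid, center, fo=1.0, etot=-9.53, minus_tse=0.0):
    site = HydrationSite(sid, np.asarray(center, float), fo)
    site.thermo.Etot = etot
    site.thermo.minus_TSe = minus_tse
    return site


def _pose(positions, radius=1.7):
    positions = np.atleast_2d(np.asarray(positions, float))
    return LigandPose(
        positions, np.full(len(positions), radius),
        [f"C{i+1}" for i in range(len(positions))],
    )


def test_far_site_retained_and_coincident_displaced():
    sites = [_site(1, [10.0, 0, 0]), _site(2, [0.0, 0, 0])]
    pose = _pose([[0.0, 0.001, 0.0]])
    for mode in ("envelope", "center_distance"):
        flags = flag_displaced(sites, pose, mode=mode)
        assert flags == [False, True]


def test_empty_ligand_rejected():
    with pytest.raises(ValueError):
        flag_displaced([_site(1, [0, 0, 0])], None)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(-8, 8, allow_nan=False),
            st.floats(-8, 8, allow_nan=False),
            st.floats(-8, 8, allow_nan=False),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_envelope_displaces_superset_of_center_distance(centers):
    """At equal probe, the envelope criterion displaces every site the
    center-distance criterion does."""
    sites = [_site(i, c) for i, c in enumerate(centers)]
    pose = _pose([[0.0, 0.0, 0.0], [3.0, 1.0, -2.0]])
    env = flag_displaced(sites, pose, mode="envelope")
    cen = flag_displaced(sites, pose, mode="center_distance")
    assert all(e or not c for e, c in zip(env, cen))


def test_synthetic_scenario_flags_planted_subset(three_site_run):
    sites = three_site_run["sites"]
    pose = three_site_run["ligand"]
    specs = three_site_run["specs"]
    flags = flag_displaced(sites, pose)
    displaced_planted = set()
    for site, flag in zip(sites, flags):
        if flag:
            d = [np.linalg.norm(site.center - s.center) for s in specs]
            displaced_planted.add(int(np.argmin(d)))
    assert displaced_planted == set(three_site_run["scenario"]["displace_subset"])


# ---------------------------------------------------------------------------
# crystal matching

def test_crystal_water_at_center_matches():
    sites = [_site(1, [0, 0, 0])]
    pose = _pose([[0, 0, 2.0]])
    crystal = CrystalWaterSet(np.array([[0.0, 0.0, 0.0]]))
    flags, fraction, _ = match_crystal_waters(sites, crystal, pose)
    assert flags == [True] and fraction == 1.0


def test_crystal_water_beyond_cutoff_no_match():
    sites = [_site(1, [0, 0, 0])]
    pose = _pose([[0, 0, 2.0]])
    crystal = CrystalWaterSet(np.array([[2.5, 0.0, 0.0]]))
    flags, fraction, _ = match_crystal_waters(sites, crystal, pose)
    assert flags == [False] and fraction == 0.0


def test_empty_crystal_set_flagged():
    sites = [_site(1, [0, 0, 0])]
    pose = _pose([[0, 0, 2.0]])
    flags, fraction, notes = match_crystal_waters(
        sites, CrystalWaterSet(np.zeros((0, 3))), pose
    )
    assert fraction == 0.0
    assert "no crystal waters in shell" in notes


def test_crystal_match_one_to_one_greedy():
    """One crystal water cannot consume two sites; nearest pair wins."""
    sites = [_site(1, [0, 0, 0]), _site(2, [1.0, 0, 0])]
    pose = _pose([[0.5, 0, 2.0]])
    crystal = CrystalWaterSet(np.array([[0.2, 0.0, 0.0]]))
    flags, fraction, _ = match_crystal_waters(sites, crystal, pose)
    assert flags == [True, False]
    assert fraction == pytest.approx(0.5)


def test_crystal_match_invariant_under_relabeling():
    pose = _pose([[0.5, 0, 2.0]])
    crystal = CrystalWaterSet(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    a = [_site(1, [0, 0, 0]), _site(2, [1.0, 0, 0])]
    b = [_site(1, [1.0, 0, 0]), _site(2, [0.0, 0, 0])]
    fa = match_crystal_waters(a, crystal, pose)[1]
    fb = match_crystal_waters(b, crystal, pose)[1]
    assert fa == fb == 1.0


def test_planted_coincidence_fraction(three_site_run):
    """Crystal waters at 2 of 3 planted centers + 1 decoy: fraction 2/3."""
    sites = three_site_run["sites"]
    flags, fraction, _ = match_crystal_waters(
        sites, three_site_run["crystal"], three_site_run["ligand"]
    )
    assert fraction == pytest.approx(2.0 / 3.0)
    assert sum(flags) == 2


# ---------------------------------------------------------------------------
# binding contributions

def test_no_displaced_sites_zero_contributions(bulk):
    sites = [_site(1, [0, 0, 0], etot=-12.0)]
    dh, tds, _ = binding_contributions(sites, [False], bulk)
    assert dh == 0.0 and tds == 0.0


def test_bulk_like_displaced_site_zero_enthalpy(bulk):
    sites = [_site(1, [0, 0, 0], fo=1.0, etot=bulk.Etot_bulk)]
    dh, _, _ = binding_contributions(sites, [True], bulk)
    assert dh == pytest.approx(0.0, abs=1e-12)


def test_entropy_penalty_becomes_gain_on_displacement(bulk):
    sites = [_site(1, [0, 0, 0], fo=1.0, minus_tse=1.5)]
    _, tds, _ = binding_contributions(sites, [True], bulk)
    assert tds == pytest.approx(-1.5)


def test_contributions_additive_over_disjoint_subsets(bulk):
    sites = [
        _site(1, [0, 0, 0], fo=0.8, etot=-11.0, minus_tse=2.0),
        _site(2, [4, 0, 0], fo=0.6, etot=-8.0, minus_tse=1.0),
        _site(3, [8, 0, 0], fo=0.4, etot=-9.0, minus_tse=0.5),
    ]
    dh_all, tds_all, _ = binding_contributions(sites, [True, True, False], bulk)
    dh_1, tds_1, _ = binding_contributions(sites, [True, False, False], bulk)
    dh_2, tds_2, _ = binding_contributions(sites, [False, True, False], bulk)
    assert dh_all == pytest.approx(dh_1 + dh_2, abs=1e-12)
    assert tds_all == pytest.approx(tds_1 + tds_2, abs=1e-12)


def test_missing_entropy_excluded_and_logged(bulk):
    site = _site(1, [0, 0, 0], fo=1.0, etot=-11.0)
    site.thermo.minus_TSe = None
    dh, tds, notes = binding_contributions([site], [True], bulk)
    assert dh == pytest.approx(1.0 * (bulk.Etot_bulk + 11.0))
    assert tds == 0.0
    assert any("entropy missing" in n for n in notes)


def test_occupancy_weighting_switchable(bulk):
    sites = [_site(1, [0, 0, 0], fo=0.5, etot=-11.0, minus_tse=2.0)]
    dh_w, tds_w, _ = binding_contributions(sites, [True], bulk)
    dh_u, tds_u, _ = binding_contributions(
        sites, [True], bulk, occupancy_weighted=False
    )
    assert dh_w == pytest.approx(0.5 * dh_u)
    assert tds_w == pytest.approx(0.5 * tds_u)


# ---------------------------------------------------------------------------
# apo–holo comparison

def _thermo_site(sid, center, etot, minus_tse, nsw=0.5, nww=2.0):
    site = _site(sid, center, etot=etot, minus_tse=minus_tse)
    site.thermo.NswHB = nsw
    site.thermo.NwwHB = nww
    return site


def test_identical_site_lists_pair_with_zero_deltas():
    apo = [_thermo_site(1, [0, 0, 0], -10.0, 1.5),
           _thermo_site(2, [4, 0, 0], -9.0, 2.0)]
    holo = [_thermo_site(1, [0, 0, 0], -10.0, 1.5),
            _thermo_site(2, [4, 0, 0], -9.0, 2.0)]
    pairs, lost, gained = match_apo_holo(apo, holo)
    assert len(pairs) == 2 and not lost and not gained
    for p in pairs:
        assert p.center_distance == 0.0
        assert p.delta_Etot == 0.0
        assert p.delta_minus_TSe == 0.0


def test_unmatched_sites_reported_lost_and_gained():
    apo = [_thermo_site(1, [0, 0, 0], -10.0, 1.5)]
    holo = [_thermo_site(7, [5.0, 0, 0], -9.0, 1.0)]
    pairs, lost, gained = match_apo_holo(apo, holo)
    assert pairs == []
    assert lost == [1] and gained == [7]


def test_pairing_is_one_to_one_nearest_first():
    apo = [_thermo_site(1, [0, 0, 0], -10.0, 1.5),
           _thermo_site(2, [1.0, 0, 0], -9.0, 1.0)]
    holo = [_thermo_site(3, [0.2, 0, 0], -9.5, 1.2)]
    pairs, lost, _ = match_apo_holo(apo, holo)
    assert len(pairs) == 1
    assert pairs[0].apo_site_id == 1
    assert lost == [2]


def test_tightened_holo_site_raises_minus_tse(bulk):
    """Halving a site's positional spread in holo makes Δ(−TSᵉ) > 0."""
    rng = np.random.default_rng(31)

    def entropy_site(sid, sigma):
        members = [
            WaterObservation(
                f, 0, sigma * rng.standard_normal(3),
                (lambda v: v / np.linalg.norm(v))(rng.standard_normal(4)),
            )
            for f in range(500)
        ]
        site = HydrationSite(sid, np.zeros(3), 1.0, members)
        tr, orient, total = site_entropy(site, bulk, n_frames=500)
        site.thermo.minus_TSe = total
        site.thermo.Etot = -10.0
        return site

    apo = [entropy_site(1, 0.4)]
    holo = [entropy_site(1, 0.2)]
    pairs, _, _ = match_apo_holo(apo, holo)
    assert pairs[0].delta_minus_TSe > 0
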