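"""Residue classification and the 0.5-nm contact census."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coronastat as cs
from coronastat.contacts import (CLASSES, ResidueClass, census_timeseries,
                                 classify_residue, contact_census)
from coronastat.model import Atom, ProteinStructure, System, SurfaceModel, \
    Trajectory
from conftest import random_toy_system
from oracles import brute_force_census


@pytest.mark.parametrize("code,expected", [
    ("LEU", ResidueClass.HYDROPHOBIC),
    ("ALA", ResidueClass.HYDROPHOBIC),
    ("TRP", ResidueClass.HYDROPHOBIC),
    ("ASP", ResidueClass.CHARGED),
    ("LYS", ResidueClass.CHARGED),
    ("SER", ResidueClass.NONCHARGED),
    ("HIS", ResidueClass.NONCHARGED),
    ("GLY", ResidueClass.NONCHARGED),
])
def test_classification(code, expected):
    assert classify_residue(code) == expected


def test_every_standard_residue_has_exactly_one_class():
    from coronastat.synthetic import _ONE_TO_THREE
    for code in _ONE_TO_THREE.values():
        assert classify_residue(code) in CLASSES


def test_unknown_code_is_echoed():
    with pytest.raises(ValueError, match="XYZ"):
        classify_residue("XYZ")


def _flat_sheet(n=25):
    atoms = [Atom(i, "C", "C", "GRA", i + 1, "S",
                  np.array([0.2 * (i % 5), 0.2 * (i // 5), 0.0]),
                  role="lattice") for i in range(n)]
    return SurfaceModel(atoms)


def _tripeptide(z_leu, z_ser, z_asp):
    atoms = []
    for i, (res, z) in enumerate([("LEU", z_leu), ("SER", z_ser),
                                  ("ASP", z_asp)]):
        atoms.append(Atom(i, "CA", "C", res, i + 1, "A",
                          np.array([0.4, 0.2 + 0.1 * i, z])))
    return ProteinStructure(atoms)


def test_tripeptide_census_matches_brute_force():
    protein = _tripeptide(0.3, 0.7, 0.9)
    sheet = _flat_sheet()
    sys_ = System(protein, sheet)
    census = contact_census(sys_, cutoff=0.5)
    assert census.counts == {"hydrophobic": 1, "noncharged_hydrophilic": 0,
                             "charged_hydrophilic": 0}
    oracle = brute_force_census(protein, sheet.coords, 0.5)
    assert {(c, s) for c, s, *_ in census.contact_residues} == oracle


def test_assembled_gap_exceeds_cutoff(helix_on_pg):
    census = contact_census(helix_on_pg, cutoff=0.5)
    assert census.total == 0


def test_min_distances_listed_within_cutoff():
    sys_ = System(_tripeptide(0.2, 0.45, 0.3), _flat_sheet())
    census = contact_census(sys_, cutoff=0.5)
    assert census.total == 3
    for *_, dmin in census.contact_residues:
        assert dmin <= 0.5


def test_census_equals_brute_force_on_random_systems():
    """k-d-tree census equals the all-pairs scan (exact set equality)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        sys_ = random_toy_system(rng)
        census = contact_census(sys_, cutoff=0.5)
        oracle = brute_force_census(sys_.protein, sys_.surface.coords, 0.5)
        assert {(c, s) for c, s, *_ in census.contact_residues} == oracle


@settings(max_examples=30, deadline=None)
@given(c1=st.floats(0.1, 1.2), c2=st.floats(0.1, 1.2), seed=st.integers(0, 50))
def test_census_monotone_in_cutoff(c1, c2, seed):
    lo, hi = sorted((c1, c2))
    rng = np.random.default_rng(seed)
    sys_ = random_toy_system(rng)
    small = contact_census(sys_, cutoff=lo)
    big = contact_census(sys_, cutoff=hi)
    set_small = {(c, s) for c, s, *_ in small.contact_residues}
    set_big = {(c, s) for c, s, *_ in big.contact_residues}
    assert set_small <= set_big


def test_rigid_motion_invariance():
    rng = np.random.default_rng(7)
    sys_ = random_toy_system(rng)
    before = contact_census(sys_, cutoff=0.5)
    # rotate both bodies together and translate
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    shift = np.array([1.0, -2.0, 3.0])
    for grp in (sys_.protein, sys_.surface):
        grp.set_coords(grp.coords @ rot.T + shift)
    after = contact_census(sys_, cutoff=0.5)
    assert before.counts == after.counts


def test_hydrogens_do_not_change_census():
    protein = _tripeptide(0.3, 0.7, 0.9)
    with_h = ProteinStructure(
        protein.atoms + [Atom(9, "HA", "H", "LEU", 1, "A",
                              np.array([0.4, 0.2, 0.05]))]
    )
    sheet = _flat_sheet()
    a = contact_census(System(protein, sheet))
    b = contact_census(System(with_h, sheet))
    assert a.counts == b.counts


class TestCensusTimeseries:
    def test_constant_trajectory(self):
        sys_ = System(_tripeptide(0.3, 0.7, 0.9), _flat_sheet())
        traj = Trajectory(sys_, [sys_.coords.copy() for _ in range(5)])
        means, sems = census_timeseries(traj, window="all")
        assert means["hydrophobic"] == 1.0
        assert all(v == 0.0 for v in sems.values())

    def test_toggling_contact_averages_to_half(self):
        sys_ = System(_tripeptide(0.3, 0.7, 0.9), _flat_sheet())
        near = sys_.coords.copy()
        far = sys_.coords.copy()
        far[0, 2] = 2.0  # LEU CA out of range on odd frames
        traj = Trajectory(sys_, [near, far] * 3)
        means, _ = census_timeseries(traj, window="all")
        assert means["hydrophobic"] == pytest.approx(0.5)

    def test_jitter_around_contact_pose(self):
        rng = np.random.default_rng(3)
        sys_ = System(_tripeptide(0.2, 0.35, 0.4), _flat_sheet())
        base = sys_.coords
        pose = contact_census(sys_, cutoff=0.5)
        frames = [base + rng.normal(0, 0.01, base.shape) for _ in range(50)]
        means, _ = census_timeseries(Trajectory(sys_, frames), window="all")
        assert means["total"] == pytest.approx(pose.total, abs=1.0)
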