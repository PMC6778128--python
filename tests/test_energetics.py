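"""Lennard-Jones/Coulomb decomposition against brute-force oracles."""

import numpy as np
import pytest

import coronastat as cs
from coronastat.energetics import (COULOMB_F, EnergyDecomposition,
                                   ForceFieldTable, energy_timeseries,
                                   interaction_energy, pair_lj)
from coronastat.model import Atom, ProteinStructure, System, SurfaceModel, \
    Trajectory
from oracles import brute_force_energy

FF = ForceFieldTable.default()


def _pair_system(distance, protein_kwargs=None, surface_role="lattice",
                 surface_el="C"):
    p = ProteinStructure([Atom(0, "CA", "C", "ALA", 1, "A",
                               np.zeros(3), **(protein_kwargs or {}))])
    s = SurfaceModel([Atom(0, "C", surface_el, "GRA", 1, "S",
                           np.array([distance, 0.0, 0.0]),
                           role=surface_role)])
    return System(p, s)


def test_lj_zero_crossing_and_minimum():
    sig_c = np.sqrt(FF.params["C_pro"][0] * FF.params["C_gra"][0])
    eps_c = np.sqrt(FF.params["C_pro"][1] * FF.params["C_gra"][1])
    at_sigma = interaction_energy(_pair_system(sig_c), ff=FF, cutoff=5.0)
    assert at_sigma.lj == pytest.approx(0.0, abs=1e-12)
    at_min = interaction_energy(_pair_system(2 ** (1 / 6) * sig_c), ff=FF,
                                cutoff=5.0)
    assert at_min.lj == pytest.approx(-eps_c, abs=1e-12)


def test_neutral_surface_has_exactly_zero_coulomb(helix_on_pg):
    """Pristine graphene carbons are neutral, so Coulomb vanishes."""
    traj = cs.make_adsorption_path(helix_on_pg, 1.0, 0.3, n_steps=3)
    for f in traj.frames:
        e = interaction_energy(helix_on_pg, f, FF)
        assert e.coulomb == 0.0


def test_matches_brute_force_on_random_toys():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n_p, n_s = 12, 18
        res = ["ALA", "ASP", "LYS", "SER", "GLU"]
        patoms = [Atom(i, "CA" if i % 3 else "NZ", "C" if i % 3 else "N",
                       res[i % 5] if i % 3 else "LYS", i + 1, "A",
                       rng.uniform(0, 1.8, 3)) for i in range(n_p)]
        satoms = []
        for i in range(n_s):
            role = ("lattice", "C") if i % 4 else ("hydroxyl_O", "O")
            satoms.append(Atom(i, "C", role[1], "GRA", i + 1, "S",
                               np.array([*rng.uniform(0, 1.8, 2), 0.0]),
                               role=role[0]))
        sys_ = System(ProteinStructure(patoms), SurfaceModel(satoms))
        e = interaction_energy(sys_, ff=FF, cutoff=1.2)
        ps, pe, pq = FF.arrays(patoms)
        ss, se, sq = FF.arrays(satoms)
        lj, coul = brute_force_energy(
            sys_.protein.coords, sys_.surface.coords,
            ps, pe, pq, ss, se, sq, 1.2
        )
        assert e.lj == pytest.approx(lj, abs=1e-9)
        assert e.coulomb == pytest.approx(coul, abs=1e-9)


def test_coulomb_linear_in_charge():
    table = {
        "q1": (0.3, 0.5, 0.25), "q2": (0.3, 0.5, -0.585),
    }
    r = 0.8
    e1 = COULOMB_F * 0.25 * -0.585 / r
    ff = ForceFieldTable({"C_pro": (0.3, 0.5, 0.25),
                          "C_gra": (0.3, 0.5, -0.585)})
    e = interaction_energy(_pair_system(r), ff=ff, cutoff=2.0)
    assert e.coulomb == pytest.approx(e1, rel=1e-12)
    ff2 = ForceFieldTable({"C_pro": (0.3, 0.5, 0.50),
                           "C_gra": (0.3, 0.5, -0.585)})
    e2 = interaction_energy(_pair_system(r), ff=ff2, cutoff=2.0)
    assert e2.coulomb == pytest.approx(2 * e.coulomb, rel=1e-12)


def test_lj_linear_in_epsilon():
    r = 0.35
    base = ForceFieldTable({"C_pro": (0.3, 0.4, 0.0), "C_gra": (0.3, 0.4, 0.0)})
    quad = ForceFieldTable({"C_pro": (0.3, 1.6, 0.0), "C_gra": (0.3, 0.4, 0.0)})
    e1 = interaction_energy(_pair_system(r), ff=base, cutoff=2.0).lj
    e2 = interaction_energy(_pair_system(r), ff=quad, cutoff=2.0).lj
    assert e2 == pytest.approx(2 * e1, rel=1e-12)  # sqrt(4x) = 2x


def test_rigid_motion_invariance(helix_on_pg):
    frame = cs.make_adsorption_path(helix_on_pg, 1.0, 0.35,
                                    n_steps=3).frames[-1]
    before = interaction_energy(helix_on_pg, frame, FF)
    theta = 0.9
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = frame @ rot.T + np.array([2.0, -1.0, 4.0])
    after = interaction_energy(helix_on_pg, moved, FF)
    assert after.lj == pytest.approx(before.lj, rel=1e-9)
    assert after.n_pairs_in_cutoff == before.n_pairs_in_cutoff


def test_cutoff_tail_is_small():
    """On a compact converged toy, doubling the cutoff barely moves LJ."""
    from coronastat.surfaces import SurfaceSpec
    peptide = cs.make_ideal_helix("LKAL")
    pg = cs.build_graphene(SurfaceSpec(kind="graphene", dims=(2.0, 2.0),
                                       oh_fraction=0.0))
    sys_ = cs.assemble_system(peptide, pg, gap=1.0)
    frame = cs.make_adsorption_path(sys_, 1.0, 0.35, n_steps=3).frames[-1]
    e12 = interaction_energy(sys_, frame, FF, cutoff=1.2)
    e24 = interaction_energy(sys_, frame, FF, cutoff=2.4)
    assert abs(e24.lj - e12.lj) < 0.05 * abs(e12.lj)


def test_minimum_image_sees_periodic_neighbor():
    sys_ = _pair_system(0.4)
    sys_.box = np.array([3.0, 3.0, 3.0])
    direct = interaction_energy(sys_, ff=FF, cutoff=1.0)
    # move the surface atom across the boundary: image distance unchanged
    sys_.surface.atoms[0].coord = np.array([0.4 - 3.0, 0.0, 0.0])
    wrapped = interaction_energy(sys_, ff=FF, cutoff=1.0)
    assert wrapped.lj == pytest.approx(direct.lj, rel=1e-12)


def test_untyped_atom_named_in_error():
    p = ProteinStructure([Atom(0, "XX", "Xe", "ALA", 1, "A", np.zeros(3))])
    s = SurfaceModel([Atom(0, "C", "C", "GRA", 1, "S",
                           np.array([0.5, 0, 0]), role="lattice")])
    with pytest.raises(KeyError, match="untyped"):
        interaction_energy(System(p, s), ff=FF)


class TestTimeseries:
    def test_constant_trajectory_sem_zero(self, helix_on_pg):
        frame = cs.make_adsorption_path(helix_on_pg, 1.0, 0.4,
                                        n_steps=2).frames[-1]
        traj = Trajectory(helix_on_pg, [frame.copy() for _ in range(4)])
        out = energy_timeseries(traj, window="all", ff=FF)
        assert out["lj"][1] == 0.0
        assert out["coulomb"][1] == 0.0

    def test_approach_has_a_minimum(self, helix_on_pg):
        """LJ drops on approach, then rises into core overlap."""
        traj = cs.make_adsorption_path(helix_on_pg, 1.2, 0.18, n_steps=14)
        lj = [interaction_energy(helix_on_pg, f, FF).lj for f in traj.frames]
        k = int(np.argmin(lj))
        assert 0 < k < len(lj) - 1
        assert lj[k] < lj[0] and lj[k] < lj[-1]
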