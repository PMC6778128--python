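from __future__ import annotations

import numpy as np
import pytest

import coronastat as cs
from coronastat.model import Atom, ProteinStructure, System
from coronastat.surfaces import SurfaceSpec


@pytest.fixture(scope="session")
def ideal_helix20():
    return cs.make_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def amphipathic_helix_seq():
    # hydrophobic every 3-4 positions: one face of the wheel
    return "LKKLLKELLEKLLKKLLE"


@pytest.fixture(scope="session")
def hairpin12():
    return cs.make_hairpin("V" * 12)


@pytest.fixture(scope="session")
def toy_protein():
    return cs.make_toy_protein(seed=0)


@pytest.fixture(scope="session")
def small_pg_sheet():
    return cs.build_graphene(
        SurfaceSpec(kind="graphene", dims=(6.0, 5.0), oh_fraction=0.0)
    )


@pytest.fixture(scope="session")
def helix_on_pg(small_pg_sheet):
    helix = cs.make_ideal_helix("LKALEEKLKALEEKLKAL")
    return cs.assemble_system(helix, small_pg_sheet, gap=1.0)


def single_atom_protein(coord, res_name="ALA", name="CA", element="C"):
    atom = Atom(0, name, element, res_name, 1, "A", np.asarray(coord, float))
    return ProteinStructure([atom])


def random_toy_system(rng, n_protein=10, n_surface=15):
    """Small random protein-above-surface system for oracle comparisons."""
    res_names = ["LEU", "SER", "ASP", "GLY", "LYS", "PHE", "THR", "GLU",
                 "VAL", "ASN"]
    atoms = []
    for i in range(n_protein):
        coord = rng.uniform([0, 0, 0.1], [2.0, 2.0, 1.2])
        atoms.append(Atom(i, "CA", "C", res_names[i % len(res_names)],
                          i + 1, "A", coord))
    protein = ProteinStructure(atoms)
    surf_atoms = [
        Atom(i, "C", "C", "GRA", i + 1, "S",
             np.array([*rng.uniform([0, 0], [2.0, 2.0]), 0.0]),
             role="lattice")
        for i in range(n_surface)
    ]
    surface = cs.SurfaceModel(surf_atoms)
    return System(protein, surface)
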