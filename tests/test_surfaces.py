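"""Graphene/gold builders: lattices, decoration patterns, assembly."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import coronastat as cs
from coronastat.surfaces import (OH_FRACTION_ALL, OH_FRACTION_HALF,
                                 SurfaceSpec, THIOL_SITE, assemble_system,
                                 build_gold_slab, build_graphene)


def graphene(dims=(8.5, 6.5), **kw):
    return build_graphene(SurfaceSpec(kind="graphene", dims=dims, **kw))


class TestGraphene:
    def test_pristine_has_no_hydroxyls_and_fills_dims(self):
        g = graphene(oh_fraction=0.0)
        assert len(g.hydroxyl_oxygens()) == 0
        coords = g.coords
        assert coords[:, 0].max() <= 8.5 and coords[:, 1].max() <= 6.5
        assert coords[:, 0].max() > 8.0 and coords[:, 1].max() > 6.0
        # sheet is coplanar before decoration
        assert np.abs(coords[:, 2]).max() < 1e-9

    def test_bond_length_on_lattice(self):
        g = graphene(dims=(2.0, 2.0))
        coords = g.coords[:, :2]
        d, _ = cKDTree(coords).query(coords, k=2)
        np.testing.assert_allclose(d[:, 1].min(), 0.142, atol=1e-6)

    def test_half_coverage_is_half_of_full(self):
        full = graphene(oh_fraction=OH_FRACTION_ALL, seed=7)
        half = graphene(oh_fraction=OH_FRACTION_HALF, seed=7)
        n_full = len(full.hydroxyl_oxygens())
        n_half = len(half.hydroxyl_oxygens())
        assert abs(n_half - round(n_full / 2)) <= 1

    def test_hydroxyl_count_matches_fraction(self):
        g = graphene(oh_fraction=0.05, seed=3)
        n_c = sum(1 for a in g.atoms if a.element == "C")
        assert len(g.hydroxyl_oxygens()) == round(0.05 * 2 * n_c)

    def test_stripes_band_membership_exhaustive(self):
        d = 0.8
        g = graphene(oh_fraction=OH_FRACTION_HALF, pattern="stripes",
                     stripe_interval_d=d, seed=5)
        xs = np.array([a.coord[0] for a in g.atoms if a.element == "C"])
        x0 = xs.min()
        for a in g.atoms:
            if a.role == "hydroxyl_O":
                band = int(np.floor((a.coord[0] - x0) / d))
                assert band % 2 == 0, f"OH at x={a.coord[0]:.3f} off-band"

    def test_janus_restricted_to_half_plane(self):
        g = graphene(oh_fraction=OH_FRACTION_HALF, pattern="janus", seed=5)
        xs = np.array([a.coord[0] for a in g.atoms if a.element == "C"])
        mid = (xs.min() + xs.max()) / 2
        for a in g.atoms:
            if a.role == "hydroxyl_O":
                assert a.coord[0] < mid

    def test_patterns_keep_oh_count_fixed(self):
        counts = {
            pat: len(graphene(oh_fraction=OH_FRACTION_HALF, pattern=pat,
                              stripe_interval_d=2.3,
                              seed=11).hydroxyl_oxygens())
            for pat in ("uniform_random", "janus", "stripes")
        }
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_seed_determinism_and_variation(self):
        a = graphene(oh_fraction=0.02, seed=1)
        b = graphene(oh_fraction=0.02, seed=1)
        c = graphene(oh_fraction=0.02, seed=2)
        pos = lambda g: np.array([x.coord for x in g.hydroxyl_oxygens()])
        np.testing.assert_array_equal(pos(a), pos(b))
        assert pos(a).shape == pos(c).shape
        assert not np.array_equal(pos(a), pos(c))

    def test_half_coverage_mean_nn_spacing(self):
        """Mean nearest-neighbour OH spacing ~0.6 nm at half coverage."""
        spacings = []
        for seed in (0, 1, 2):
            g = graphene(oh_fraction=OH_FRACTION_HALF, seed=seed)
            pos = np.array([a.coord for a in g.hydroxyl_oxygens()])
            for face in (1, -1):
                p = pos[np.sign(pos[:, 2]) == face][:, :2]
                d, _ = cKDTree(p).query(p, k=2)
                spacings.extend(d[:, 1])
        assert np.mean(spacings) == pytest.approx(0.6, rel=0.2)

    def test_stripe_interval_larger_than_sheet_raises(self):
        with pytest.raises(ValueError, match="interval"):
            graphene(oh_fraction=0.01, pattern="stripes",
                     stripe_interval_d=20.0)


class TestGold:
    def test_balanced_coating_has_equal_chain_counts(self):
        au = build_gold_slab(SurfaceSpec(kind="gold", dims=(8.0, 6.0),
                                         chain_ratio=0.5, seed=4))
        n_anchors = len({a.res_seq for a in au.atoms if a.role and
                         "thiol" in a.role or a.role == "hydroxyl_O"
                         if a.res_name == "THI"})
        n_so = len({a.res_seq for a in au.atoms
                    if a.role == "hydroxyl_O" and a.res_name == "THI"})
        n_sc = len({a.res_seq for a in au.atoms if a.res_name == "THI"}) - n_so
        assert abs(n_so - n_sc) <= 1

    def test_pure_methyl_coating_has_no_hydroxyls(self):
        au = build_gold_slab(SurfaceSpec(kind="gold", dims=(8.0, 6.0),
                                         chain_ratio=0.0))
        assert len(au.hydroxyl_oxygens()) == 0

    def test_anchor_count_matches_lattice_enumeration(self):
        dims = (8.0, 6.0)
        au = build_gold_slab(SurfaceSpec(kind="gold", dims=dims,
                                         chain_ratio=0.5))
        n_anchors = len({a.res_seq for a in au.atoms if a.res_name == "THI"})
        # independent enumeration of the hexagonal anchor lattice
        count = 0
        dy = THIOL_SITE * np.sqrt(3) / 2
        j = 0
        while j * dy <= dims[1] + 1e-9:
            x = (THIOL_SITE / 2) if j % 2 else 0.0
            while x <= dims[0] + 1e-9:
                count += 1
                x += THIOL_SITE
            j += 1
        assert n_anchors == count

    def test_slab_is_three_layers(self):
        au = build_gold_slab(SurfaceSpec(kind="gold", dims=(3.0, 3.0)))
        z = {round(a.coord[2], 6) for a in au.atoms if a.element == "Au"}
        assert len(z) == 3

    def test_bad_chain_ratio_rejected(self):
        with pytest.raises(ValueError, match="chain_ratio"):
            SurfaceSpec(kind="gold", dims=(3.0, 3.0), chain_ratio=1.5)


class TestAssembly:
    def test_single_atom_gap_exact(self, small_pg_sheet):
        from conftest import single_atom_protein
        p = single_atom_protein([5.0, 5.0, 9.0])
        sys_ = assemble_system(p, small_pg_sheet, gap=1.0)
        z = sys_.protein.coords[0, 2]
        assert z - small_pg_sheet.top_z == pytest.approx(1.0, abs=1e-6)

    def test_min_distance_brute_force(self, helix_on_pg):
        """Assembled min heavy-atom height above the decoration plane
        equals the requested gap, by exhaustive scan."""
        heavy = helix_on_pg.protein.heavy_indices()
        pc = helix_on_pg.protein.coords[heavy]
        dmin = min(c[2] - helix_on_pg.surface.top_z for c in pc)
        assert dmin == pytest.approx(1.0, abs=1e-6)

    def test_oversized_protein_warns_not_errors(self, ideal_helix20):
        tiny = cs.build_graphene(SurfaceSpec(kind="graphene", dims=(0.5, 0.5)))
        with pytest.warns(UserWarning, match="footprint"):
            assemble_system(ideal_helix20, tiny, gap=1.0)

    def test_box_encloses_everything(self, helix_on_pg):
        allc = helix_on_pg.coords
        extent = allc.max(axis=0) - allc.min(axis=0)
        assert np.all(helix_on_pg.box >= extent)
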