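"""Build the nanomaterial surface models: graphene with hydroxyl
patterns, and a thiol-coated gold slab.

Prints atom and hydroxyl counts for each surface and the mean
nearest-neighbour hydroxyl spacing at half coverage — at the default
half-coverage density that spacing is ~0.6 nm, the regime where
hydroxyls are dense enough to blanket the sheet uniformly.
"""

import numpy as np
from scipy.spatial import cKDTree

from coronastat import SurfaceSpec, build_gold_slab, build_graphene
from coronastat.surfaces import OH_FRACTION_HALF

for label, kwargs in [
    ("pristine graphene (PG)", dict(oh_fraction=0.0)),
    ("G-half-OH (random)", dict(oh_fraction=OH_FRACTION_HALF, seed=1)),
    ("Janus (one modified half)", dict(oh_fraction=OH_FRACTION_HALF,
                                       pattern="janus", seed=1)),
    ("striped, d = 0.8 nm", dict(oh_fraction=OH_FRACTION_HALF,
                                 pattern="stripes", stripe_interval_d=0.8,
                                 seed=1)),
]:
    sheet = build_graphene(SurfaceSpec(kind="graphene", dims=(8.5, 6.5),
                                       **kwargs))
    print(f"{label:<28s} {len(sheet):5d} atoms, "
          f"{len(sheet.hydroxyl_oxygens()):3d} hydroxyls")

half = build_graphene(SurfaceSpec(kind="graphene", dims=(8.5, 6.5),
                                  oh_fraction=OH_FRACTION_HALF, seed=1))
pos = np.array([a.coord for a in half.hydroxyl_oxygens()])
top = pos[pos[:, 2] > 0][:, :2]
d, _ = cKDTree(top).query(top, k=2)
print(f"mean OH nearest-neighbour spacing (top face): {d[:, 1].mean():.2f} nm")

gold = build_gold_slab(SurfaceSpec(kind="gold", dims=(8.0, 6.0),
                                   chain_ratio=0.5, seed=1))
n_so = len({a.res_seq for a in gold.atoms if a.role == "hydroxyl_O"})
n_anchors = len({a.res_seq for a in gold.atoms if a.res_name == "THI"})
print(f"Au-half-OH slab: {len(gold)} atoms, {n_anchors} thiol chains "
      f"({n_so} hydroxyl-terminated)")
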