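"""Parametric nanomaterial surface constructors.

Builds the two substrate families used in protein-corona adsorption
studies: honeycomb graphene sheets with hydroxyl decoration (uniformly
random, Janus half-plane, or alternating stripes of width *d*) and
fcc(111) gold slabs coated with alkanethiol chains — hydrophobic
S-(CH2)7-CH3 ("SC") and hydroxyl-terminated S-(CH2)7-CH2OH ("SO").

All coordinates are nm; the surface normal is +z.  Decoration is a
pure function of the spec (including its seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Atom, ProteinStructure, SurfaceModel, System

__all__ = [
    "SurfaceSpec",
    "build_graphene",
    "build_gold_slab",
    "build_surface",
    "assemble_system",
]

CC_BOND = 0.142          # graphene C-C, nm
CO_BOND = 0.149          # graphene C-OH, nm, along the normal
OH_BOND = 0.096
AU_NN = 0.2885           # Au fcc(111) in-plane nearest-neighbour spacing
AU_LAYER_DZ = 0.2355     # fcc(111) interlayer spacing
THIOL_SITE = 0.497       # sqrt(3)xsqrt(3) R30 thiol lattice constant
AU_S_BOND = 0.24
CC_RISE = 0.127          # all-trans alkane axial rise per C-C bond
CC_ZIG = 0.044           # lateral zigzag half-amplitude

#: default per-site OH fractions; the half-coverage value reproduces the
#: ~0.6 nm mean nearest-neighbour OH spacing of a half-hydroxylated sheet
#: (2-D Poisson nearest-neighbour distance 1/(2 sqrt(rho)))
OH_FRACTION_ALL = 0.036
OH_FRACTION_HALF = 0.018


@dataclass
class SurfaceSpec:
    """Parameters of a generated surface.

    ``oh_fraction`` is the fraction of decorable sites (every lattice
    carbon, on each decorated face) carrying a hydroxyl; for gold,
    ``chain_ratio`` is the fraction of thiol anchor sites carrying the
    hydroxyl-terminated SO chain (the rest carry SC).
    ``stripe_interval_d`` is the alternating-band width *d*.
    """

    kind: str = "graphene"                     # graphene | gold
    dims: tuple[float, float] = (8.5, 6.5)     # basal plane, nm
    oh_fraction: float = 0.0
    pattern: str = "uniform_random"            # uniform_random | janus | stripes
    stripe_interval_d: float = 0.8
    seed: int = 0
    chain_ratio: float = 0.0
    double_sided: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("graphene", "gold"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if not (0.0 <= self.oh_fraction <= 1.0):
            raise ValueError("oh_fraction must be in [0, 1]")
        if not (0.0 <= self.chain_ratio <= 1.0):
            raise ValueError("chain_ratio must be in [0, 1]")
        if self.pattern not in ("uniform_random", "janus", "stripes"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "stripes" and self.stripe_interval_d <= 0:
            raise ValueError("stripe_interval_d must be > 0 for stripes")
        if min(self.dims) <= 0:
            raise ValueError("dims must be positive")


def _honeycomb(dims: tuple[float, float]) -> np.ndarray:
    """Honeycomb lattice points with bond length CC_BOND filling dims."""
    lx, ly = dims
    ax, ay = 3 * CC_BOND, np.sqrt(3) * CC_BOND     # rectangular 4-atom cell
    basis = np.array(
        [[0.0, 0.0], [CC_BOND, 0.0],
         [1.5 * CC_BOND, ay / 2], [2.5 * CC_BOND, ay / 2]]
    )
    nx, ny = int(np.ceil(lx / ax)), int(np.ceil(ly / ay))
    pts = []
    for i in range(nx):
        for j in range(ny):
            for b in basis:
                x, y = i * ax + b[0], j * ay + b[1]
                if x <= lx + 1e-9 and y <= ly + 1e-9:
                    pts.append((x, y))
    return np.asarray(pts)


def _pick_sites(spec: SurfaceSpec, xy: np.ndarray, n_sites: int,
                long_axis: int) -> np.ndarray:
    """Choose decorated site indices according to the spec's pattern.

    ``xy`` has one row per decorable site (a lattice position, repeated
    per face for double-sided decoration).  The global count is always
    round(oh_fraction * n_sites) so that patterns at equal oh_fraction
    are controlled comparisons differing only in placement.
    """
    count = int(round(spec.oh_fraction * n_sites))
    if count == 0:
        return np.array([], dtype=int)
    if n_sites == 0:
        raise ValueError("oh_fraction > 0 but no decorable sites")
    x = xy[:, long_axis]
    if spec.pattern == "uniform_random":
        eligible = np.arange(len(xy))
    elif spec.pattern == "janus":
        eligible = np.nonzero(x < (x.min() + x.max()) / 2)[0]
    else:  # stripes
        length = x.max() - x.min()
        if spec.stripe_interval_d > length:
            raise ValueError(
                f"stripe interval d={spec.stripe_interval_d} nm exceeds sheet "
                f"length {length:.2f} nm"
            )
        band = np.floor((x - x.min()) / spec.stripe_interval_d).astype(int)
        eligible = np.nonzero(band % 2 == 0)[0]
    if count > len(eligible):
        raise ValueError(
            f"oh_fraction={spec.oh_fraction} needs {count} sites but pattern "
            f"{spec.pattern!r} exposes only {len(eligible)}"
        )
    rng = np.random.default_rng(spec.seed)
    return rng.choice(eligible, size=count, replace=False)


def build_graphene(spec: SurfaceSpec) -> SurfaceModel:
    """Build a (possibly hydroxylated) graphene sheet in the z=0 plane.

    Hydroxyl oxygens sit at ±CO_BOND along z above/below the decorated
    carbon, with the O-H bond continuing along the normal.  Decorated
    carbons are tagged ``hydroxyl_C`` (they carry the ipso partial
    charge in the energy model); bare carbons are ``lattice``.
    """
    if spec.kind != "graphene":
        raise ValueError("spec.kind must be 'graphene'")
    lattice = _honeycomb(spec.dims)
    n_c = len(lattice)
    long_axis = 0 if spec.dims[0] >= spec.dims[1] else 1
    faces = [1.0, -1.0] if spec.double_sided else [1.0]
    # decorable sites: (carbon, face) pairs, carbon-major ordering
    site_xy = np.repeat(lattice, len(faces), axis=0)
    chosen = _pick_sites(spec, site_xy, n_c * len(faces), long_axis)

    atoms: list[Atom] = []
    decorated_c = {int(s) // len(faces) for s in chosen}
    for i, (x, y) in enumerate(lattice):
        role = "hydroxyl_C" if i in decorated_c else "lattice"
        atoms.append(Atom(len(atoms), "C", "C", "GRA", i + 1, "S",
                          np.array([x, y, 0.0]), role=role))
    for s in sorted(int(v) for v in chosen):
        ci, fi = divmod(s, len(faces))
        sign = faces[fi]
        x, y = lattice[ci]
        o = np.array([x, y, sign * CO_BOND])
        h = o + np.array([0.0, 0.0, sign * OH_BOND])
        atoms.append(Atom(len(atoms), "OH", "O", "GRA", ci + 1, "S", o,
                          role="hydroxyl_O"))
        atoms.append(Atom(len(atoms), "HO", "H", "GRA", ci + 1, "S", h,
                          role="hydroxyl_H"))
    return SurfaceModel(atoms, spec=spec)


def _hex_lattice(dims: tuple[float, float], a: float) -> np.ndarray:
    """Hexagonal lattice with spacing ``a`` filling dims."""
    lx, ly = dims
    dy = a * np.sqrt(3) / 2
    pts = []
    j = 0
    y = 0.0
    while y <= ly + 1e-9:
        x0 = (a / 2) if j % 2 else 0.0
        x = x0
        while x <= lx + 1e-9:
            pts.append((x, y))
            x += a
        j += 1
        y = j * dy
    return np.asarray(pts)


def _alkane_chain(anchor: np.ndarray, n_carbons: int, terminal_oh: bool):
    """All-trans alkanethiol chain standing along +z from an Au anchor."""
    coords = [("S", "S", anchor + np.array([0, 0, AU_S_BOND]), "thiol_chain")]
    z = anchor[2] + AU_S_BOND
    for k in range(n_carbons):
        z += CC_RISE
        zig = CC_ZIG if k % 2 == 0 else -CC_ZIG
        coords.append(("C", "C", np.array([anchor[0] + zig, anchor[1], z]),
                       "thiol_chain"))
    if terminal_oh:
        tip = coords[-1][2]
        o = tip + np.array([0.0, 0.0, 0.143])
        coords.append(("OH", "O", o, "hydroxyl_O"))
        coords.append(("HO", "H", o + np.array([0.0, 0.0, OH_BOND]),
                       "hydroxyl_H"))
    return coords


def build_gold_slab(spec: SurfaceSpec) -> SurfaceModel:
    """Build a 3-layer fcc(111) Au slab with an alkanethiol monolayer.

    Thiols occupy a sqrt(3)xsqrt(3) R30 sublattice (0.497 nm spacing);
    a ``chain_ratio`` fraction of them are hydroxyl-terminated SO
    chains, the rest methyl-terminated SC chains.  Only three layers
    are kept: with a 1.2 nm interaction cutoff, deeper layers are
    energetically negligible.
    """
    if spec.kind != "gold":
        raise ValueError("spec.kind must be 'gold'")
    atoms: list[Atom] = []
    shift = np.array([AU_NN / 2, AU_NN / (2 * np.sqrt(3))])
    for layer in range(3):
        z = -layer * AU_LAYER_DZ
        for x, y in _hex_lattice(spec.dims, AU_NN) + layer * shift:
            if x <= spec.dims[0] + 1e-9 and y <= spec.dims[1] + 1e-9:
                atoms.append(Atom(len(atoms), "AU", "Au", "AUS", 1, "S",
                                  np.array([x, y, z]), role="lattice"))
    anchors = _hex_lattice(spec.dims, THIOL_SITE)
    n_so = int(round(spec.chain_ratio * len(anchors)))
    order = _anchor_order(spec, anchors)
    so_set = set(order[:n_so].tolist())
    for i, (x, y) in enumerate(anchors):
        chain = _alkane_chain(np.array([x, y, 0.0]), 8, terminal_oh=i in so_set)
        for name, el, c, role in chain:
            atoms.append(Atom(len(atoms), name, el, "THI", i + 1, "S", c,
                              role=role))
    return SurfaceModel(atoms, spec=spec)


def _anchor_order(spec: SurfaceSpec, anchors: np.ndarray) -> np.ndarray:
    """Order anchor sites for SO assignment (pattern-aware)."""
    long_axis = 0 if spec.dims[0] >= spec.dims[1] else 1
    if spec.pattern == "janus":
        return np.argsort(anchors[:, long_axis], kind="stable")
    if spec.pattern == "stripes":
        band = np.floor(anchors[:, long_axis] / spec.stripe_interval_d).astype(int)
        return np.argsort(band % 2, kind="stable")
    rng = np.random.default_rng(spec.seed)
    return rng.permutation(len(anchors))


def build_surface(spec: SurfaceSpec) -> SurfaceModel:
    """Dispatch on ``spec.kind``."""
    return build_graphene(spec) if spec.kind == "graphene" else build_gold_slab(spec)


def assemble_system(
    protein: ProteinStructure,
    surface: SurfaceModel,
    gap: float = 1.0,
    box_padding: tuple[float, float, float] = (1.0, 1.0, 1.0),
    center_lateral: bool = True,
) -> System:
    """Place a protein above a surface at a given initial separation.

    The protein is rigidly translated so that the minimum distance
    between any protein heavy atom and the top decoration plane of the
    surface equals ``gap`` (default 1.0 nm, the conventional initial
    separation of adsorption simulations).  The orthorhombic box is set
    from the joint extents plus ``box_padding``.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    protein = protein.copy()
    heavy = protein.heavy_indices()
    pc = protein.coords
    top = surface.top_z
    dz = (top + gap) - pc[heavy, 2].min()
    shift = np.array([0.0, 0.0, dz])
    if center_lateral:
        scoords = surface.coords
        s_mid = (scoords[:, :2].min(axis=0) + scoords[:, :2].max(axis=0)) / 2
        p_mid = (pc[heavy, :2].min(axis=0) + pc[heavy, :2].max(axis=0)) / 2
        shift[:2] = s_mid - p_mid
    protein.translate(shift)
    footprint = protein.coords[heavy, :2]
    extent = footprint.max(axis=0) - footprint.min(axis=0)
    sdim = (surface.spec.dims if surface.spec is not None
            else surface.coords[:, :2].max(axis=0))
    if extent[0] > sdim[0] or extent[1] > sdim[1]:
        warnings.warn(
            "protein footprint exceeds the surface basal plane", stacklevel=2
        )
    allc = np.vstack([protein.coords, surface.coords])
    box = allc.max(axis=0) - allc.min(axis=0) + 2 * np.asarray(box_padding)
    return System(protein, surface, box=box)
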