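"""Shrake–Rupley solvent-accessible surface area and contact surface area.

The contact surface area (CSA) between a protein and a surface is the
buried interface area

    CSA = (SASA_protein + SASA_surface - SASA_complex) / 2,

computed from three SASA evaluations with identical probe radius and
quadrature.  SASA uses the Shrake–Rupley rolling-probe construction
with a deterministic golden-spiral point set, so results are
bit-reproducible at fixed ``n_points``.

Units: nm and nm².  Default probe radius 0.14 nm (water).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import System, Trajectory, select_window

__all__ = [
    "SASAResult",
    "CSAValue",
    "compute_sasa",
    "sasa_of_group",
    "compute_csa",
    "csa_timeseries",
    "vdw_radius",
]

#: Bondi van der Waals radii (nm), used when hydrogens are present
BONDI = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
         "P": 0.180, "F": 0.147, "Au": 0.166}
#: united-atom heavy radii, used when hydrogens are absent
UNITED = {"C": 0.187, "N": 0.165, "O": 0.150, "S": 0.185, "P": 0.190,
          "Au": 0.166}

#: negative-CSA clamp tolerance, nm² (quadrature noise)
CSA_NOISE = 0.01


def vdw_radius(element: str, united: bool = False) -> float:
    table = UNITED if united else BONDI
    try:
        return table[element.capitalize() if len(element) > 1 else element.upper()]
    except KeyError:
        return 0.17 if united else 0.152


@dataclass
class SASAResult:
    total: float            # nm²
    per_atom: np.ndarray    # nm²
    probe_radius: float
    n_sphere_points: int


@dataclass
class CSAValue:
    value: float            # nm²
    components: tuple[float, float, float]   # (SASA_pro, SASA_sur, SASA_complex)


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 0.14,
    n_points: int = 960,
) -> SASAResult:
    """Shrake–Rupley SASA of a set of spheres.

    Each atom's accessible area is the fraction of golden-spiral test
    points on its probe-inflated sphere (radius r_i + probe) that are
    not inside any neighbour's probe-inflated sphere, times the full
    sphere area.  Neighbour lookup uses a k-d tree; the result is
    identical to the all-pairs scan.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    n = len(coords)
    tree = cKDTree(coords)
    close = tree.query_pairs(1e-6)
    if close:
        i, j = next(iter(close))
        raise ValueError(f"coincident atoms {i} and {j} (distance < 1e-6 nm)")
    sphere = _golden_spiral(n_points)
    big = radii + probe
    rmax = big.max()
    # sparse neighbor lists: pairs whose inflated spheres overlap
    pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d < big[pairs[:, 0]] + big[pairs[:, 1]]
        pairs = pairs[keep]
    nbr: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        nbr[i].append(j)
        nbr[j].append(i)
    per_atom = np.empty(n)
    for i in range(n):
        ri = big[i]
        if not nbr[i]:
            per_atom[i] = 4.0 * np.pi * ri * ri
            continue
        nc = coords[nbr[i]]
        nr2 = big[nbr[i]] ** 2
        pts = coords[i] + ri * sphere
        # (n_points, k) squared distances via the expanded form
        d2 = (
            (pts * pts).sum(axis=1)[:, None]
            - 2.0 * pts @ nc.T
            + (nc * nc).sum(axis=1)[None, :]
        )
        frac = 1.0 - (d2 < nr2[None, :]).any(axis=1).mean()
        per_atom[i] = frac * 4.0 * np.pi * ri * ri
    return SASAResult(float(per_atom.sum()), per_atom, probe, n_points)


def _group_arrays(group, heavy_only: str = "auto"):
    """Coordinates and radii for an atom group.

    ``heavy_only='auto'``: if the group contains hydrogens they are
    kept and Bondi radii used; otherwise heavy atoms get united-atom
    radii (the probe then accounts for the implicit hydrogens).
    """
    atoms = list(group.atoms)
    has_h = any(not a.is_heavy for a in atoms)
    united = not has_h or heavy_only == "always"
    if united:
        atoms = [a for a in atoms if a.is_heavy]
    coords = np.array([a.coord for a in atoms])
    radii = np.array([vdw_radius(a.element, united=united) for a in atoms])
    return coords, radii


def sasa_of_group(group, probe: float = 0.14, n_points: int = 960) -> SASAResult:
    coords, radii = _group_arrays(group)
    return compute_sasa(coords, radii, probe=probe, n_points=n_points)


def compute_csa(
    system: System,
    frame: np.ndarray | None = None,
    probe: float = 0.14,
    n_points: int = 960,
) -> CSAValue:
    """Contact surface area of a protein-surface system at one frame.

    Three SASA evaluations with identical probe and point count:
    protein alone, surface alone, and the complex.  Negative values
    within the quadrature-noise tolerance are clamped to zero.
    """
    pc, pr = _group_arrays(system.protein)
    sc, sr = _group_arrays(system.surface)
    if frame is not None:
        pc, sc = system.split_frame(frame)
        pc, sc = np.asarray(pc, float), np.asarray(sc, float)
    s_pro = compute_sasa(pc, pr, probe, n_points).total
    s_sur = compute_sasa(sc, sr, probe, n_points).total
    s_cpx = compute_sasa(
        np.vstack([pc, sc]), np.concatenate([pr, sr]), probe, n_points
    ).total
    value = (s_pro + s_sur - s_cpx) / 2.0
    if -CSA_NOISE <= value < 0.0:
        value = 0.0
    return CSAValue(value, (s_pro, s_sur, s_cpx))


def csa_timeseries(
    traj: Trajectory | list[Trajectory],
    system: System | None = None,
    window: str | None = "last:0.25",
    probe: float = 0.14,
    n_points: int = 960,
):
    """Per-frame CSA over a window, reduced to (mean, sem, per_frame).

    With a list of replica trajectories, each replica is averaged over
    its window first and the s.e.m. is taken across replicas.
    """
    if isinstance(traj, list):
        means = [
            csa_timeseries(t, system, window, probe, n_points)[0] for t in traj
        ]
        means = np.asarray(means)
        sem = (means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0
        return float(means.mean()), float(sem), means
    sys_ = system if system is not None else traj.topology
    if not isinstance(sys_, System):
        raise ValueError("csa_timeseries needs a System topology")
    idx = select_window(len(traj), window)
    vals = np.array(
        [compute_csa(sys_, traj.frames[k], probe, n_points).value for k in idx]
    )
    sem = (vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), float(sem), vals
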