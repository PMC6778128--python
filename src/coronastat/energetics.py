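"""Protein–surface Lennard-Jones and Coulomb energy decomposition.

Direct pairwise sum over intermolecular (protein atom, surface atom)
pairs within a cutoff (default 1.2 nm):

    E_LJ   = Σ 4ε_ij [(σ_ij/r)^12 - (σ_ij/r)^6]
    E_Coul = Σ f q_i q_j / (ε_r r),     f = 138.935 kJ·mol⁻¹·nm·e⁻²

with geometric combination for both σ and ε (OPLS convention) and
plain-cutoff electrostatics (ε_r = 1) — this quantifies the direct
protein–surface term only, with no reciprocal-space or solvent
contribution.  The minimum-image convention is applied when the
system carries a box.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, System, Trajectory, select_window

__all__ = ["ForceFieldTable", "EnergyDecomposition", "interaction_energy",
           "energy_timeseries", "COULOMB_F"]

COULOMB_F = 138.935458  # kJ·mol⁻¹·nm·e⁻²

# per-(residue, atom-name) overrides carrying the coarse formal charges
_PROTEIN_SPECIAL = {
    ("ASP", "OD1"): "O_carboxylate", ("ASP", "OD2"): "O_carboxylate",
    ("GLU", "OE1"): "O_carboxylate", ("GLU", "OE2"): "O_carboxylate",
    ("LYS", "NZ"): "N_lysine",
    ("ARG", "NH1"): "N_arginine", ("ARG", "NH2"): "N_arginine",
}
_PROTEIN_BY_ELEMENT = {"C": "C_pro", "N": "N_pro", "O": "O_pro",
                       "S": "S_pro", "P": "P_pro", "H": "H_pro"}
_SURFACE_BY_ROLE = {
    ("lattice", "C"): "C_gra",
    ("hydroxyl_C", "C"): "C_ipso",
    ("hydroxyl_O", "O"): "O_oh",
    ("hydroxyl_H", "H"): "H_oh",
    ("lattice", "Au"): "AU",
    ("thiol_chain", "S"): "S_thiol",
    ("thiol_chain", "C"): "C_thiol",
}


class ForceFieldTable:
    """Per-atom-type (σ, ε, q) with a resolver from atoms to types.

    Loaded from a plain-text TSV (``type  sigma_nm  epsilon_kJmol
    charge_e``); the packaged default covers protein heavy atoms plus
    the graphene / hydroxyl / gold / thiol surface chemistry.
    """

    def __init__(self, params: dict[str, tuple[float, float, float]],
                 name: str = "builtin"):
        for t, (s, e, _q) in params.items():
            if s <= 0 or e < 0:
                raise ValueError(f"type {t}: sigma must be > 0, epsilon >= 0")
        self.params = dict(params)
        self.name = name

    @classmethod
    def from_file(cls, path) -> "ForceFieldTable":
        params = {}
        for ln in open(path):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            t, s, e, q = ln.split()
            params[t] = (float(s), float(e), float(q))
        return cls(params, name=str(path))

    @classmethod
    def default(cls) -> "ForceFieldTable":
        ref = resources.files("coronastat") / "data" / "forcefield.tsv"
        with resources.as_file(ref) as p:
            return cls.from_file(p)

    def type_of(self, atom: Atom) -> str:
        if atom.role is not None:
            key = (atom.role, atom.element.capitalize()
                   if len(atom.element) > 1 else atom.element.upper())
            t = _SURFACE_BY_ROLE.get(key)
            if t is None:
                raise KeyError(
                    f"untyped surface atom {atom.serial} "
                    f"(role={atom.role!r}, element={atom.element!r})"
                )
            return t
        t = _PROTEIN_SPECIAL.get((atom.res_name.upper(), atom.name.upper()))
        if t is None:
            t = _PROTEIN_BY_ELEMENT.get(atom.element.upper())
        if t is None:
            raise KeyError(
                f"untyped atom {atom.serial} {atom.res_name}:{atom.name} "
                f"(element {atom.element!r})"
            )
        return t

    def arrays(self, atoms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sigma, epsilon, charge) arrays for an atom sequence."""
        sig, eps, chg = [], [], []
        for a in atoms:
            s, e, q = self.params[self.type_of(a)]
            sig.append(s)
            eps.append(e)
            chg.append(q)
        return np.array(sig), np.array(eps), np.array(chg)


@dataclass
class EnergyDecomposition:
    lj: float                # kJ/mol
    coulomb: float           # kJ/mol
    cutoff: float            # nm
    n_pairs_in_cutoff: int


def pair_lj(r: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def interaction_energy(
    system: System,
    frame: np.ndarray | None = None,
    ff: ForceFieldTable | None = None,
    cutoff: float = 1.2,
    eps_r: float = 1.0,
) -> EnergyDecomposition:
    """LJ + Coulomb sum over protein-surface pairs within the cutoff."""
    if ff is None:
        ff = ForceFieldTable.default()
    if frame is not None:
        pc, sc = system.split_frame(frame)
    else:
        pc, sc = system.protein.coords, system.surface.coords
    ps, pe, pq = ff.arrays(system.protein.atoms)
    ss, se, sq = ff.arrays(system.surface.atoms)
    box = system.box
    if box is None:
        ii, jj, r = _pairs_tree(pc, sc, cutoff)
    else:
        ii, jj, r = _pairs_minimum_image(pc, sc, cutoff, box)
    if len(r) == 0:
        return EnergyDecomposition(0.0, 0.0, cutoff, 0)
    sig = np.sqrt(ps[ii] * ss[jj])
    eps = np.sqrt(pe[ii] * se[jj])
    lj = float(pair_lj(r, sig, eps).sum())
    coul = float((COULOMB_F * pq[ii] * sq[jj] / (eps_r * r)).sum())
    return EnergyDecomposition(lj, coul, cutoff, len(r))


def _pairs_tree(pc, sc, cutoff):
    tp, ts = cKDTree(pc), cKDTree(sc)
    pairs = tp.query_ball_tree(ts, cutoff)
    ii, jj = [], []
    for i, js in enumerate(pairs):
        ii.extend([i] * len(js))
        jj.extend(js)
    ii, jj = np.asarray(ii, int), np.asarray(jj, int)
    r = np.linalg.norm(pc[ii] - sc[jj], axis=1) if len(ii) else np.empty(0)
    return ii, jj, r


def _pairs_minimum_image(pc, sc, cutoff, box):
    d = pc[:, None, :] - sc[None, :, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=2)
    ii, jj = np.nonzero(r <= cutoff)
    return ii, jj, r[ii, jj]


def energy_timeseries(
    traj: Trajectory,
    system: System | None = None,
    ff: ForceFieldTable | None = None,
    cutoff: float = 1.2,
    window: str | None = "last:0.25",
):
    """Mean ± s.e.m. of the LJ and Coulomb components over a window."""
    sys_ = system if system is not None else traj.topology
    if not isinstance(sys_, System):
        raise ValueError("energy_timeseries needs a System topology")
    if ff is None:
        ff = ForceFieldTable.default()
    idx = select_window(len(traj), window)
    lj, coul = [], []
    for k in idx:
        e = interaction_energy(sys_, traj.frames[k], ff, cutoff)
        lj.append(e.lj)
        coul.append(e.coulomb)
    out = {}
    for name, v in (("lj", np.asarray(lj)), ("coulomb", np.asarray(coul))):
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out[name] = (float(v.mean()), sem)
    return out
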