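"""Synthetic inputs with known ground truth.

Desk-scale stand-ins for the cluster-scale simulation outputs the
analysis consumes: ideal-geometry peptides (α-helix, β-hairpin) built
from canonical backbone internal coordinates, equilibrium "jitter"
trajectories with a prescribed per-residue fluctuation σ (so every
downstream statistic has a closed-form expectation), and rigid-body
adsorption paths that carry a protein from beyond contact range onto a
surface.  Every stochastic generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

import numpy as np

from .model import Atom, ProteinStructure, System, Trajectory
from .secondary import _backbone, _hbond_energy, _HB_CUTOFF

__all__ = [
    "make_ideal_helix",
    "make_hairpin",
    "make_jitter_trajectory",
    "make_adsorption_path",
    "make_toy_protein",
    "parse_sequence",
]

# canonical backbone internal coordinates (nm / degrees)
B_N_CA, B_CA_C, B_C_N = 0.1458, 0.1525, 0.1329
B_C_O, B_N_H, B_CA_CB = 0.1231, 0.101, 0.153
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
SHEET_PHI, SHEET_PSI = -139.0, 135.0

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def parse_sequence(sequence) -> list[str]:
    """Accept a 1-letter string or an iterable of 3-letter codes."""
    if isinstance(sequence, str):
        try:
            return [_ONE_TO_THREE[c.upper()] for c in sequence]
        except KeyError as exc:
            raise ValueError(f"invalid residue code {exc.args[0]!r}") from None
    seq = [str(s).upper() for s in sequence]
    bad = [s for s in seq if s not in _ONE_TO_THREE.values()]
    if bad:
        raise ValueError(f"invalid residue codes {bad}")
    return seq


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors (natural extension)."""
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi, psi, omega=180.0):
    """Backbone N/CA/C/O positions for per-residue (phi, psi) lists."""
    phi = np.broadcast_to(np.asarray(phi, float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi, float), (n_res,))
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(A_N_CA_C)
    C = [CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi[i - 1]))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi[i]))
    O = []
    for i in range(n_res):
        psi_o = psi[i] + 180.0
        ref_a, ref_b, ref_c = N[i], CA[i], C[i]
        O.append(_nerf(ref_a, ref_b, ref_c, B_C_O, A_CA_C_O, psi_o))
    return N, CA, C, O


def _assemble(seq3, N, CA, C, O, chain_id="A", first_seq=1, with_h=True,
              with_cb=True):
    atoms: list[Atom] = []
    for i, res in enumerate(seq3):
        rs = first_seq + i
        parts = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]),
                 ("O", "O", O[i])]
        if with_cb and res != "GLY":
            d1 = N[i] - CA[i]
            d2 = C[i] - CA[i]
            d1 /= np.linalg.norm(d1)
            d2 /= np.linalg.norm(d2)
            perp = np.cross(d1, d2)
            perp /= np.linalg.norm(perp)
            bis = -(d1 + d2)
            bis /= np.linalg.norm(bis)
            cb = CA[i] + B_CA_CB * (bis * np.cos(np.deg2rad(54.75))
                                    + perp * np.sin(np.deg2rad(54.75)))
            parts.append(("CB", "C", cb))
        if with_h and i > 0:
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            d = u + v
            h = N[i] + B_N_H * d / np.linalg.norm(d)
            parts.append(("H", "H", h))
        for name, el, coord in parts:
            atoms.append(Atom(len(atoms), name, el, res, rs, chain_id,
                              np.asarray(coord, float)))
    return atoms


def _align_axis_z(atoms: list[Atom]) -> None:
    """Rotate so the principal CA axis lies along +z."""
    ca = np.array([a.coord for a in atoms if a.name == "CA"])
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        return
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    origin = ca.mean(axis=0)
    for a in atoms:
        a.coord = rot @ (a.coord - origin)


def make_ideal_helix(sequence, chain_id="A", first_seq=1,
                     align_z=True) -> ProteinStructure:
    """Ideal α-helix (φ = −57°, ψ = −47°) for a given sequence.

    The emergent geometry has ~0.15 nm rise and 100° twist per
    residue; with ``align_z`` the helix axis lies along +z.
    """
    seq3 = parse_sequence(sequence)
    if len(seq3) < 4:
        raise ValueError("helix needs at least 4 residues")
    N, CA, C, O = _build_backbone(len(seq3), HELIX_PHI, HELIX_PSI)
    atoms = _assemble(seq3, N, CA, C, O, chain_id, first_seq)
    if align_z:
        _align_axis_z(atoms)
    return ProteinStructure(atoms, source=f"ideal-helix[{len(seq3)}]")


def _strand(seq3, chain_id, first_seq):
    N, CA, C, O = _build_backbone(len(seq3), SHEET_PHI, SHEET_PSI)
    atoms = _assemble(seq3, N, CA, C, O, chain_id, first_seq)
    # align strand axis with +x
    ca = np.array([a.coord for a in atoms if a.name == "CA"])
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0] if vt[0][0] > 0 else -vt[0]
    z = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    else:
        rot = np.eye(3)
    origin = ca.mean(axis=0)
    for a in atoms:
        a.coord = rot @ (a.coord - origin)
    return atoms


def _interstrand_score(bb_a, bb_b) -> float:
    """Total Kabsch–Sander energy of inter-strand bonds (more negative
    is a better-registered sheet)."""
    total = 0.0
    for ea in bb_a:
        for eb in bb_b:
            for acc, don in ((ea, eb), (eb, ea)):
                e = _hbond_energy(acc, don)
                if e < _HB_CUTOFF:
                    total += e
    return total


def _transform_bb(bb, rot, shift):
    out = []
    for e in bb:
        out.append({k: (None if v is None else rot @ v + shift)
                    for k, v in e.items()})
    return out


def make_hairpin(sequence, chain_id="A", first_seq=1) -> ProteinStructure:
    """Antiparallel two-strand β-hairpin with a 2-residue turn.

    Strands use ideal β dihedrals (φ = −139°, ψ = +135°); the second
    strand is the 180°-rotated partner of the first, with the relative
    placement chosen by a deterministic grid search maximizing the
    number of inter-strand backbone hydrogen bonds.
    """
    seq3 = parse_sequence(sequence)
    n = len(seq3)
    if n < 8:
        raise ValueError("hairpin needs at least 8 residues")
    if n % 2:
        raise ValueError("hairpin needs an even residue count")
    m = (n - 2) // 2
    strand_a = _strand(seq3[:m], chain_id, first_seq)
    strand_b0 = _strand(seq3[m + 2:], chain_id, first_seq + m + 2)
    # candidate partner orientations that reverse the run direction:
    # 180 deg about z (flips the H-bond face) or about y (flips the pleat)
    rots = [np.diag([-1.0, -1.0, 1.0]), np.diag([-1.0, 1.0, -1.0])]
    _, bb_a = _backbone(ProteinStructure(strand_a))
    _, bb_b0 = _backbone(ProteinStructure(strand_b0))

    best, best_score = None, np.inf
    for rot in rots:
        for y0 in np.arange(0.40, 0.581, 0.01):
            for dx in np.arange(-0.7, 0.701, 0.025):
                shift = np.array([dx, y0, 0.0])
                score = _interstrand_score(bb_a, _transform_bb(bb_b0, rot, shift))
                if score < best_score:
                    best_score, best = score, (rot, shift)
    rot, shift = best

    def place_b():
        out = []
        for a in strand_b0:
            out.append(Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                            a.chain_id, rot @ a.coord + shift))
        return out

    strand_b = place_b()

    # 2-residue turn bridging strand A's C-terminus to strand B's N-terminus
    a_end = strand_a[-1].coord
    b_start = strand_b[0].coord
    mid = (a_end + b_start) / 2 + np.array([0.35, 0.0, 0.15])
    turn_atoms = []
    ts = np.linspace(0.2, 0.8, 8)
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")] * 2
    for k, t in enumerate(ts):
        # quadratic Bezier through an out-of-plane midpoint
        p = ((1 - t) ** 2) * a_end + 2 * t * (1 - t) * mid + (t**2) * b_start
        name, el = names[k]
        res_i = m if k < 4 else m + 1
        turn_atoms.append(Atom(0, name, el, seq3[res_i],
                               first_seq + res_i, chain_id, p))
    atoms = strand_a + turn_atoms + strand_b
    for i, a in enumerate(atoms):
        a.serial = i
    return ProteinStructure(atoms, source=f"ideal-hairpin[{n}]")


def make_jitter_trajectory(
    structure: ProteinStructure,
    sigma_profile,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Gaussian positional jitter about a base structure.

    ``sigma_profile`` is one σ (nm, per coordinate) per residue, or a
    scalar applied to all residues.  Displacements are independent per
    atom, frame and coordinate — not physical dynamics, but every
    fluctuation statistic has a closed form under it (e.g. RMSF = σ√3).
    """
    residues = structure.residues()
    sig = np.asarray(sigma_profile, dtype=float)
    if sig.ndim == 0:
        sig = np.full(len(residues), float(sig))
    if len(sig) != len(residues):
        raise ValueError("sigma_profile length must equal residue count")
    if np.any(sig < 0):
        raise ValueError("sigma must be >= 0")
    per_atom_sigma = np.concatenate(
        [np.full(len(r.atoms), s) for r, s in zip(residues, sig)]
    )
    base = structure.coords
    rng = np.random.default_rng(seed)
    frames = [
        base + rng.standard_normal(base.shape) * per_atom_sigma[:, None]
        for _ in range(n_frames)
    ]
    return Trajectory(structure, frames)


def make_adsorption_path(
    system: System,
    start_gap: float = 1.0,
    end_gap: float = 0.25,
    n_steps: int = 16,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Rigid approach of the protein onto the surface along −z.

    The protein translates in equal steps so that its minimum
    heavy-atom height above the top decoration plane goes from
    ``start_gap`` to ``end_gap``; the surface stays fixed.  Optional
    Gaussian jitter perturbs the protein in every frame.
    """
    if not (start_gap > end_gap > 0):
        raise ValueError("need start_gap > end_gap > 0")
    heavy = system.protein.heavy_indices()
    pc = system.protein.coords
    sc = system.surface.coords
    top = system.surface.top_z
    current = pc[heavy, 2].min() - top
    rng = np.random.default_rng(seed)
    gaps = np.linspace(start_gap, end_gap, n_steps)
    frames = []
    for g in gaps:
        p = pc.copy()
        p[:, 2] += g - current
        if jitter_sigma > 0:
            p = p + rng.standard_normal(p.shape) * jitter_sigma
        frames.append(np.vstack([p, sc]))
    return Trajectory(system, frames)


def make_toy_protein(seed: int = 0) -> ProteinStructure:
    """A 60-residue toy with three helices and one hairpin.

    Mixed sequence covering all three hydrophobicity classes; segments
    are spatially separated chains (A–D) with a continuous residue
    numbering 1–60, small enough for brute-force oracles.
    """
    helix_seqs = ["LKALEEKLKALEEK", "AFILKEQSAGDWMT", "VRDYLHNAVKQSEG"]
    hairpin_seq = "RTITVEFKGHSWDE"  # 14 residues: 2x6 strands + 2-residue turn
    parts = []
    offset = np.array([0.0, 0.0, 0.0])
    first = 1
    for k, s in enumerate(helix_seqs):
        h = make_ideal_helix(s, chain_id="ABC"[k], first_seq=first)
        h.translate(offset)
        parts.extend(h.atoms)
        offset = offset + np.array([2.5, 0.0, 0.0])
        first += len(s)
    hp = make_hairpin(hairpin_seq, chain_id="D", first_seq=first)
    hp.translate(offset + np.array([0.0, 2.0, 0.0]))
    parts.extend(hp.atoms)
    atoms = []
    for i, a in enumerate(parts):
        atoms.append(Atom(i, a.name, a.element, a.res_name, a.res_seq,
                          a.chain_id, a.coord.copy()))
    return ProteinStructure(atoms, source="toy-3helix-1hairpin")
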