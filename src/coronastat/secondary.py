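"""Simplified Kabsch–Sander secondary-structure assignment.

Backbone hydrogen bonds are detected with the classic electrostatic
criterion

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

(distances in Å), a bond existing when E < -0.5 kcal/mol.  Amide
hydrogens are reconstructed from geometry when absent.  Four labels
are produced: H (helix; 3-10 and pi folded into H), E (β-bridge /
strand), T (turn) and C (coil); priority H > E > T > C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ProteinStructure, Trajectory, select_window

__all__ = ["SSAssignment", "SSContent", "assign_ss", "ss_content", "delta_ss",
           "ss_content_timeseries"]

_HB_CUTOFF = -0.5          # kcal/mol
_Q1Q2F = 0.084 * 332.0     # kcal/mol·Å
NM_TO_A = 10.0


@dataclass
class SSAssignment:
    labels: list[str]                       # one of H/E/T/C per residue
    residues: list[tuple[str, int, str]]    # (chain, res_seq, res_name)
    missing_backbone: list[int] = field(default_factory=list)
    method: str = "kabsch-sander-lite"

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SSContent:
    helix: float
    sheet: float
    turn: float
    coil: float

    @property
    def helix_plus_sheet(self) -> float:
        return self.helix + self.sheet

    def as_dict(self) -> dict:
        return {"helix": self.helix, "sheet": self.sheet, "turn": self.turn,
                "coil": self.coil, "helix_plus_sheet": self.helix_plus_sheet}


def _backbone(structure: ProteinStructure):
    """Per-residue backbone coordinate dict (nm), amide H reconstructed."""
    residues = structure.residues()
    bb = []
    for k, res in enumerate(residues):
        entry = {}
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            entry[name] = None if a is None else a.coord
        h = res.atom("H") or res.atom("HN")
        entry["H"] = None if h is None else h.coord
        bb.append(entry)
    # reconstruct missing amide H: 0.10 nm from N, anti-bisecting
    # C(prev)-N and CA-N; first residue of a chain has no donor H
    for k, res in enumerate(residues):
        e = bb[k]
        if e["H"] is not None or e["N"] is None or e["CA"] is None:
            continue
        if k == 0 or residues[k - 1].chain_id != res.chain_id:
            continue
        cprev = bb[k - 1]["C"]
        if cprev is None:
            continue
        u = e["N"] - cprev
        v = e["N"] - e["CA"]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        d = u + v
        nrm = np.linalg.norm(d)
        if nrm > 1e-9:
            e["H"] = e["N"] + 0.10 * d / nrm
    return residues, bb


def _hbond_energy(acc, don) -> float:
    """Kabsch–Sander energy: CO of ``acc`` accepting from NH of ``don``."""
    if don["N"] is None or don["H"] is None or acc["C"] is None or acc["O"] is None:
        return 0.0
    r_on = np.linalg.norm(acc["O"] - don["N"]) * NM_TO_A
    r_ch = np.linalg.norm(acc["C"] - don["H"]) * NM_TO_A
    r_oh = np.linalg.norm(acc["O"] - don["H"]) * NM_TO_A
    r_cn = np.linalg.norm(acc["C"] - don["N"]) * NM_TO_A
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, not a bond
        return 0.0
    return _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss(structure: ProteinStructure) -> SSAssignment:
    """Assign H/E/T/C labels to every residue of a structure."""
    residues, bb = _backbone(structure)
    n = len(residues)
    labels = ["C"] * n
    missing = [k for k, e in enumerate(bb)
               if any(e[x] is None for x in ("N", "CA", "C", "O"))]
    chains = [r.chain_id for r in residues]
    per_chain = {}
    for k, c in enumerate(chains):
        per_chain.setdefault(c, []).append(k)
    short = [c for c, idx in per_chain.items() if len(idx) < 3]
    if short:
        warnings.warn(f"chains shorter than 3 residues assigned coil: {short}",
                      stacklevel=2)

    # hydrogen-bond map: hb[(i, j)] — CO of residue i accepts from NH of j
    hb = set()
    for i in range(n):
        if i in missing:
            continue
        for j in range(n):
            if abs(i - j) < 2 or j in missing:
                continue
            # only plausible pairs: CA-CA within 0.9 nm
            if np.linalg.norm(bb[i]["CA"] - bb[j]["CA"]) > 0.9:
                continue
            if _hbond_energy(bb[i], bb[j]) < _HB_CUTOFF:
                hb.add((i, j))

    def same_chain(*ks):
        return len({chains[k] for k in ks}) == 1

    helix = [False] * n
    for i in range(n - 5):
        if (i, i + 4) in hb and (i + 1, i + 5) in hb and same_chain(i, i + 5):
            for k in range(i + 1, i + 6):
                helix[k] = True
    bridge = [False] * n
    for i in range(n):
        for j in range(i + 3, n):
            anti = ((i, j) in hb and (j, i) in hb) or (
                (i - 1, j + 1) in hb and (j - 1, i + 1) in hb
                if i >= 1 and j + 1 < n else False
            )
            para = (
                ((i - 1, j) in hb and (j, i + 1) in hb if i >= 1 and i + 1 < n
                 else False)
                or ((j - 1, i) in hb and (i, j + 1) in hb if j >= 1 and j + 1 < n
                    else False)
            )
            if anti or para:
                bridge[i] = bridge[j] = True
    turn = [False] * n
    for k in (3, 4, 5):
        for i in range(n - k):
            if (i, i + k) in hb and same_chain(i, i + k):
                for t in range(i + 1, i + k):
                    turn[t] = True

    for k in range(n):
        if k in missing:
            labels[k] = "C"
        elif helix[k]:
            labels[k] = "H"
        elif bridge[k]:
            labels[k] = "E"
        elif turn[k]:
            labels[k] = "T"
    res_meta = [(r.chain_id, r.res_seq, r.res_name) for r in residues]
    return SSAssignment(labels, res_meta, missing_backbone=missing)


def ss_content(assignment: SSAssignment) -> SSContent:
    """Label counts normalized to fractions (they sum to one)."""
    if len(assignment) == 0:
        raise ValueError("empty assignment")
    n = len(assignment)
    c = {x: assignment.labels.count(x) / n for x in "HETC"}
    return SSContent(helix=c["H"], sheet=c["E"], turn=c["T"], coil=c["C"])


def delta_ss(free: SSContent, adsorbed: SSContent) -> dict:
    """Per-category change, free minus adsorbed (positive = lost on
    adsorption)."""
    return {
        "helix": free.helix - adsorbed.helix,
        "sheet": free.sheet - adsorbed.sheet,
        "turn": free.turn - adsorbed.turn,
        "coil": free.coil - adsorbed.coil,
        "helix_plus_sheet": free.helix_plus_sheet - adsorbed.helix_plus_sheet,
    }


def ss_content_timeseries(
    traj: Trajectory, window: str | None = "last:0.25"
) -> SSContent:
    """Mean secondary-structure content over a trajectory window."""
    top = traj.topology
    if not isinstance(top, ProteinStructure):
        raise ValueError("ss_content_timeseries needs a protein topology")
    idx = select_window(len(traj), window)
    acc = np.zeros(4)
    work = top.copy()
    for k in idx:
        work.set_coords(traj.frames[k])
        c = ss_content(assign_ss(work))
        acc += np.array([c.helix, c.sheet, c.turn, c.coil])
    acc /= len(idx)
    return SSContent(*acc)
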