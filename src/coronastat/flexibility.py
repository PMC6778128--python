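"""Superposition, per-residue RMSF and the ΔRMSF function-preservation
summary.

RMSF is computed after least-squares (Kabsch) superposition of every
frame onto the trajectory-average structure, iterated twice so the
reference is self-consistent.  ΔRMSF = RMSF(adsorbed) − RMSF(free) per
residue; at an active-site span, a balanced mix of positive and
negative values reads as preserved flexibility, a large majority of
rigidified (negative) residues as compromised function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ProteinStructure, Trajectory

__all__ = [
    "FlexibilityProfile",
    "DeltaRMSFSummary",
    "kabsch_superpose",
    "rmsf",
    "delta_rmsf",
]


@dataclass
class FlexibilityProfile:
    rmsf: np.ndarray               # nm, one value per selected residue
    res_seq: np.ndarray            # source residue numbers
    selection: str = "CA"
    reference: str = "iterated-mean"


@dataclass
class DeltaRMSFSummary:
    delta: np.ndarray              # adsorbed - free, nm
    res_seq: np.ndarray
    active_site_span: tuple[int, int]
    n_positive: int
    n_negative: int
    n_zero: int
    verdict: str                   # preserved | compromised | indeterminate


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference; the
    rotation is proper (det = +1).
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and mobile must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    rc, mc = ref.mean(axis=0), mob.mean(axis=0)
    p, q = ref - rc, mob - mc
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _apply(rot, trans, x):
    return x @ rot.T + trans


def _ca_selection(top: ProteinStructure):
    idx, seq = [], []
    start = 0
    for res in top.residues():
        for i, a in enumerate(res.atoms):
            if a.name == "CA":
                idx.append(start + i)
                seq.append(res.res_seq)
                break
        start += len(res.atoms)
    return np.asarray(idx, int), np.asarray(seq, int)


def rmsf(traj: Trajectory, selection: str = "CA") -> FlexibilityProfile:
    """Per-residue RMSF about the superposed trajectory mean.

    ``selection`` is ``"CA"`` (one alpha carbon per residue, the
    default) or ``"heavy"`` (per-residue mean over heavy atoms).
    """
    top = traj.topology
    if not isinstance(top, ProteinStructure):
        raise ValueError("rmsf needs a ProteinStructure topology")
    if len(traj) < 2:
        raise ValueError("rmsf needs at least 2 frames")
    if selection == "CA":
        idx, seq = _ca_selection(top)
        groups = [[i] for i in range(len(idx))]
    elif selection == "heavy":
        idx, seq, groups = _heavy_selection(top)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if len(idx) == 0:
        raise ValueError("selection is empty")
    x = np.stack([f[idx] for f in traj.frames])  # (n_frames, n_sel, 3)
    mean = x[0]
    for _ in range(2):  # superpose onto the mean, twice, to self-consistency
        fitted = np.empty_like(x)
        for k in range(x.shape[0]):
            rot, trans, _ = kabsch_superpose(mean, x[k])
            fitted[k] = _apply(rot, trans, x[k])
        mean = fitted.mean(axis=0)
        x = fitted
    dev2 = ((x - mean) ** 2).sum(axis=2)        # (n_frames, n_sel)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))
    per_res = np.array([atom_rmsf[g].mean() for g in groups])
    return FlexibilityProfile(per_res, seq, selection=selection)


def _heavy_selection(top: ProteinStructure):
    idx, seq, groups = [], [], []
    start = 0
    for res in top.residues():
        g = []
        for i, a in enumerate(res.atoms):
            if a.is_heavy:
                g.append(len(idx))
                idx.append(start + i)
        start += len(res.atoms)
        if g:
            groups.append(g)
            seq.append(res.res_seq)
    return np.asarray(idx, int), np.asarray(seq, int), groups


def delta_rmsf(
    adsorbed: FlexibilityProfile,
    free: FlexibilityProfile,
    active_site: tuple[int, int] = (136, 150),
    balance_margin: int = 2,
    compromised_majority: float = 2.0 / 3.0,
) -> DeltaRMSFSummary:
    """ΔRMSF = adsorbed − free, with an active-site verdict.

    Within the inclusive ``active_site`` residue range (source
    numbering): verdict ``preserved`` when positive and negative counts
    balance within ``balance_margin``; ``compromised`` when more than
    ``compromised_majority`` of the span is rigidified (negative);
    otherwise ``indeterminate``.
    """
    if not np.array_equal(adsorbed.res_seq, free.res_seq):
        raise ValueError("profiles cover different residue selections")
    delta = adsorbed.rmsf - free.rmsf
    lo, hi = active_site
    mask = (adsorbed.res_seq >= lo) & (adsorbed.res_seq <= hi)
    if not mask.any():
        raise ValueError(f"active site {lo}..{hi} outside residue numbering")
    span = delta[mask]
    n_pos = int((span > 0).sum())
    n_neg = int((span < 0).sum())
    n_zero = int((span == 0).sum())
    if n_neg > compromised_majority * len(span):
        verdict = "compromised"
    elif (n_pos + n_neg) > 0 and abs(n_pos - n_neg) <= balance_margin:
        verdict = "preserved"
    else:
        verdict = "indeterminate"
    return DeltaRMSFSummary(delta, adsorbed.res_seq, (lo, hi),
                            n_pos, n_neg, n_zero, verdict)
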