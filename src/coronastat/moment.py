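"""Eisenberg helical hydrophobic moment µH.

For a helix of N residues with hydrophobicities h_n placed every
δ = 100° around the helical wheel,

    µH = |Σ_n h_n · exp(i·n·δ)| / N .

A protein-level mean below 0.5 (on the Eisenberg consensus scale)
indicates homogeneously distributed hydrophobic and hydrophilic
residues — helices with no strongly amphipathic face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ProteinStructure
from .secondary import SSAssignment

__all__ = [
    "EISENBERG_CONSENSUS",
    "HydrophobicityScale",
    "MomentResult",
    "helix_uH",
    "protein_mean_uH",
    "AMPHIPATHIC_THRESHOLD",
]

AMPHIPATHIC_THRESHOLD = 0.5
DEFAULT_DELTA_DEG = 100.0

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: Eisenberg consensus (normalized) hydrophobicity scale
EISENBERG_CONSENSUS = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}


@dataclass
class HydrophobicityScale:
    values: dict
    name: str = "eisenberg-consensus"

    def __getitem__(self, residue: str) -> float:
        code = residue.strip()
        if len(code) == 3:
            code = _THREE_TO_ONE.get(code.upper(), code)
        try:
            return self.values[code.upper()]
        except KeyError:
            raise KeyError(f"residue {residue!r} missing from scale "
                           f"{self.name!r}") from None


DEFAULT_SCALE = HydrophobicityScale(EISENBERG_CONSENSUS)


@dataclass
class MomentResult:
    per_helix: list            # [(span (start,end res_seq), uH per residue)]
    mean_uH: float             # unweighted mean over helices
    mean_uH_weighted: float    # length-weighted alternative
    amphipathic_flag: bool     # True when mean_uH < 0.5 (homogeneous)


def helix_uH(
    sequence,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> float:
    """Per-residue-normalized hydrophobic moment of one helix.

    ``sequence`` is an iterable of 1- or 3-letter residue codes.
    """
    seq = list(sequence)
    if len(seq) < 2:
        raise ValueError("helix_uH needs at least 2 residues")
    h = np.array([scale[r] for r in seq])
    n = np.arange(len(seq))
    phase = np.deg2rad(delta_deg) * n
    return float(np.abs(np.sum(h * np.exp(1j * phase))) / len(seq))


def helix_spans(assignment: SSAssignment, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal runs of H labels of at least ``min_len`` residues, as
    half-open index ranges into the assignment."""
    spans = []
    start = None
    labels = assignment.labels + ["C"]  # sentinel
    for k, lab in enumerate(labels):
        if lab == "H" and start is None:
            start = k
        elif lab != "H" and start is not None:
            if k - start >= min_len:
                spans.append((start, k))
            start = None
    return spans


def protein_mean_uH(
    structure: ProteinStructure,
    assignment: SSAssignment,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    min_helix_len: int = 6,
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> MomentResult:
    """Average µH over a protein's helices.

    Helices are the maximal H runs of the secondary-structure
    assignment (length ≥ ``min_helix_len``).  The headline number is
    the unweighted mean over helices; a length-weighted mean is
    reported alongside.  The flag is True when the mean is below the
    0.5 amphiphilicity threshold.
    """
    seq3 = [r[2] for r in assignment.residues]
    spans = helix_spans(assignment, min_helix_len)
    if not spans:
        raise ValueError("no helices of sufficient length in assignment")
    per_helix = []
    for a, b in spans:
        uh = helix_uH(seq3[a:b], scale, delta_deg)
        span_seq = (assignment.residues[a][1], assignment.residues[b - 1][1])
        per_helix.append((span_seq, uh))
    vals = np.array([u for _, u in per_helix])
    lens = np.array([b - a for a, b in spans])
    mean = float(vals.mean())
    weighted = float(np.average(vals, weights=lens))
    return MomentResult(per_helix, mean, weighted,
                        amphipathic_flag=mean < AMPHIPATHIC_THRESHOLD)
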