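"""Internal data model: atoms, structures, surfaces, systems and trajectories.

Units are GROMACS-like throughout: lengths in nm, energies in kJ/mol,
times in ps, charges in units of the elementary charge.  PDB coordinates
(Å) are converted on read.  Atom indexing is 0-based internally; the
``res_seq`` of each atom is preserved verbatim from the source file so
that residue ranges quoted against the source numbering (e.g. an active
site "residues 136–150") keep their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "AtomGroup",
    "ProteinStructure",
    "SurfaceModel",
    "System",
    "Trajectory",
    "Residue",
]

#: elements treated as hydrogen for "heavy atom" selections
_HYDROGEN = {"H", "D"}


@dataclass
class Atom:
    """A single atom.

    ``coord`` is a length-3 float array in nm.  ``role`` tags surface
    chemistry (``lattice``, ``hydroxyl_O``, ``hydroxyl_H``,
    ``thiol_chain``) and is ``None`` for protein atoms.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: np.ndarray
    occupancy: float | None = None
    bfactor: float | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom {self.serial}: coord must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: non-finite coordinate")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass
class Residue:
    """A contiguous run of atoms sharing (chain_id, res_seq, res_name)."""

    chain_id: str
    res_seq: int
    res_name: str
    atoms: list[Atom]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class AtomGroup:
    """Base container: an ordered list of atoms with array views."""

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise ValueError("AtomGroup requires at least one atom")
        self.atoms: list[Atom] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm (copy)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, coords):
            a.coord = c.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def residues(self) -> list[Residue]:
        """Group atoms into contiguous (chain_id, res_seq, res_name) runs."""
        out: list[Residue] = []
        key = None
        for a in self.atoms:
            k = (a.chain_id, a.res_seq, a.res_name)
            if k != key:
                out.append(Residue(a.chain_id, a.res_seq, a.res_name, []))
                key = k
            out[-1].atoms.append(a)
        return out

    def translate(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        for a in self.atoms:
            a.coord = a.coord + vec


class ProteinStructure(AtomGroup):
    """A protein (or any molecular solute) read from file or built in code."""

    def __init__(self, atoms: Sequence[Atom], source: str = "<memory>"):
        super().__init__(atoms)
        self.source = source

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def sequence(self) -> list[str]:
        """3-letter residue codes in chain order."""
        return [r.res_name for r in self.residues()]

    def copy(self) -> "ProteinStructure":
        atoms = [
            Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                 a.coord.copy(), a.occupancy, a.bfactor, a.role)
            for a in self.atoms
        ]
        return ProteinStructure(atoms, source=self.source)


class SurfaceModel(AtomGroup):
    """Generated nanomaterial coordinates plus per-atom chemistry roles.

    The surface normal is +z by convention; ``spec`` records the
    generating parameters (see :mod:`coronastat.surfaces`).
    """

    def __init__(self, atoms: Sequence[Atom], spec=None):
        super().__init__(atoms)
        self.spec = spec

    @property
    def top_z(self) -> float:
        """z of the highest surface atom (top decoration plane)."""
        return max(a.coord[2] for a in self.atoms)

    def hydroxyl_oxygens(self) -> list[Atom]:
        return [a for a in self.atoms if a.role == "hydroxyl_O"]


class System:
    """A protein positioned above a surface, optionally in an orthorhombic box."""

    def __init__(
        self,
        protein: ProteinStructure,
        surface: SurfaceModel,
        box: np.ndarray | None = None,
    ):
        self.protein = protein
        self.surface = surface
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and self.box.shape != (3,):
            raise ValueError("box must be a 3-vector (orthorhombic)")

    @property
    def n_atoms(self) -> int:
        return len(self.protein) + len(self.surface)

    @property
    def coords(self) -> np.ndarray:
        """Protein atoms first, then surface atoms."""
        return np.vstack([self.protein.coords, self.surface.coords])

    def split_frame(self, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a full-system frame into (protein, surface) coordinate blocks."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (self.n_atoms, 3):
            raise ValueError(
                f"frame has {frame.shape[0]} atoms, system has {self.n_atoms}"
            )
        np_ = len(self.protein)
        return frame[:np_], frame[np_:]


class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``topology`` may be a :class:`ProteinStructure`, :class:`SurfaceModel`
    or :class:`System`; every frame is an (n_atoms, 3) array in nm.
    """

    def __init__(
        self,
        topology,
        frames: Iterable[np.ndarray],
        times: Sequence[float] | None = None,
    ):
        self.topology = topology
        n = topology.n_atoms if isinstance(topology, System) else len(topology)
        self.frames: list[np.ndarray] = []
        for k, f in enumerate(frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k}: has {f.shape[0]} atoms, topology has {n}"
                )
            self.frames.append(f)
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        self.times = None if times is None else list(times)
        if self.times is not None:
            if len(self.times) != len(self.frames):
                raise ValueError("times length must match frame count")
            if any(b <= a for a, b in zip(self.times, self.times[1:])):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].shape[0]


def select_window(n_frames: int, window: str | slice | None) -> list[int]:
    """Resolve a frame-selection window to a list of frame indices.

    Accepted forms: ``None``/``"all"`` (every frame), ``"last"``
    (final frame only), ``"last:FRAC"`` (final FRAC of frames, e.g.
    ``"last:0.25"``), ``"frames:A:B"`` (half-open index range) or a
    Python slice.
    """
    if window is None or window == "all":
        return list(range(n_frames))
    if isinstance(window, slice):
        idx = list(range(n_frames))[window]
    elif window == "last":
        idx = [n_frames - 1]
    elif isinstance(window, str) and window.startswith("last:"):
        frac = float(window.split(":", 1)[1])
        if not 0 < frac <= 1:
            raise ValueError(f"window fraction must be in (0, 1]: {window!r}")
        k = max(1, int(round(frac * n_frames)))
        idx = list(range(n_frames - k, n_frames))
    elif isinstance(window, str) and window.startswith("frames:"):
        _, a, b = window.split(":")
        idx = list(range(int(a), min(int(b), n_frames)))
    else:
        raise ValueError(f"unrecognized window {window!r}")
    if not idx:
        raise ValueError(f"window {window!r} selects no frames")
    return idx
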