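"""Structure and trajectory I/O.

Reads PDB (via gemmi), multi-model PDB trajectories, XYZ and a minimal
GRO dialect, and normalizes everything into the internal nm-based data
model.  Writers emit the same three formats; JSON/TSV report output
lives here too.

Conventions: PDB and XYZ files are in Å and converted to nm on read;
GRO is natively nm.  Water and monatomic-ion records are dropped on
PDB read by default.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import gemmi
import numpy as np

from .model import Atom, ProteinStructure, System, Trajectory

__all__ = [
    "read_pdb",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_report",
]

A_TO_NM = 0.1

# residue names removed on read (solvent and common monatomic ions)
_SOLVENT = {
    "HOH", "WAT", "H2O", "TIP", "TIP3", "SOL",
    "NA", "CL", "K", "MG", "CA", "ZN", "SOD", "CLA", "POT", "NA+", "CL-",
}


def _element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name."""
    s = name.strip()
    if not s:
        raise ValueError("cannot infer element from empty atom name")
    if s[0].isdigit():
        s = s.lstrip("0123456789")
    # two-letter symbols that actually occur in this package's systems
    two = s[:2].upper()
    if two in {"AU", "FE", "MG", "ZN", "CL", "BR", "SE", "NA"} and len(s) >= 2:
        return two.capitalize()
    return s[0].upper()


def read_pdb(
    path: str | Path,
    chain_filter: set[str] | None = None,
    drop_solvent: bool = True,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Coordinates are converted Å → nm.  Waters and monatomic ions are
    dropped by default; ``chain_filter`` keeps only the listed chains
    (e.g. ``{"A"}`` to use a single chain of a multi-chain entry).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise ValueError(f"unparseable PDB record in {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        cid = chain.name.strip() or " "
        if chain_filter is not None and cid not in chain_filter:
            continue
        for res in chain:
            if drop_solvent and res.name.strip().upper() in _SOLVENT:
                continue
            for at in res:
                el = at.element.name if at.element and at.element.name != "X" else ""
                if not el:
                    el = _element_from_name(at.name)
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name.strip(),
                        element=el,
                        res_name=res.name.strip(),
                        res_seq=res.seqid.num,
                        chain_id=cid,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]) * A_TO_NM,
                        occupancy=at.occ,
                        bfactor=at.b_iso,
                    )
                )
                serial += 1
    if not atoms:
        if chain_filter is not None:
            raise ValueError(
                f"{path}: no atoms left after chain filter {sorted(chain_filter)}"
            )
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return ProteinStructure(atoms, source=str(path))


# ---------------------------------------------------------------------------
# trajectory readers


def _read_pdb_frames(path: Path, n_atoms: int) -> tuple[list[np.ndarray], None]:
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    frames = []
    for k, model in enumerate(st):
        coords = []
        for chain in model:
            for res in chain:
                for at in res:
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        arr = np.asarray(coords) * A_TO_NM
        if arr.shape[0] != n_atoms:
            raise ValueError(
                f"{path}: frame {k} has {arr.shape[0]} atoms, expected {n_atoms}"
            )
        frames.append(arr)
    return frames, None


def _read_xyz_frames(path: Path, n_atoms: int):
    frames, times = [], []
    lines = path.read_text().splitlines()
    i, k = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                t = None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame {k}")
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in block]
        ) * A_TO_NM
        if coords.shape[0] != n_atoms:
            raise ValueError(
                f"{path}: frame {k} has {coords.shape[0]} atoms, expected {n_atoms}"
            )
        frames.append(coords)
        times.append(t)
        i += 2 + n
        k += 1
    times_out = times if all(t is not None for t in times) and times else None
    return frames, times_out


def _read_gro_frames(path: Path, n_atoms: int):
    """Minimal GRO dialect: title / natoms / atom lines / box line, repeated."""
    frames, boxes = [], []
    lines = path.read_text().splitlines()
    i, k = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{i + 2}: expected atom count") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame {k}")
        # field width = spacing between decimal points (supports the
        # standard %8.3f and high-precision %9.4f conventions)
        p1 = block[0].index(".", 20)
        w = block[0].index(".", p1 + 1) - p1
        coords = np.array(
            [[float(ln[20:20 + w]), float(ln[20 + w:20 + 2 * w]),
              float(ln[20 + 2 * w:20 + 3 * w])] for ln in block]
        )
        if coords.shape[0] != n_atoms:
            raise ValueError(
                f"{path}: frame {k} has {coords.shape[0]} atoms, expected {n_atoms}"
            )
        frames.append(coords)
        box_line = lines[i + 2 + n].split() if i + 2 + n < len(lines) else []
        boxes.append([float(x) for x in box_line[:3]] if len(box_line) >= 3 else None)
        i += 3 + n
        k += 1
    return frames, boxes


def read_trajectory(path: str | Path, topology) -> Trajectory:
    """Read a multi-frame coordinate file against a fixed topology.

    Supports multi-model PDB, XYZ (time on the comment line as ``t=``)
    and a minimal GRO dialect.  A GRO box line populates
    ``System.box`` when the topology is a :class:`System`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    n_atoms = topology.n_atoms if isinstance(topology, System) else len(topology)
    suffix = path.suffix.lower()
    times = None
    if suffix == ".pdb":
        frames, times = _read_pdb_frames(path, n_atoms)
    elif suffix == ".xyz":
        frames, times = _read_xyz_frames(path, n_atoms)
    elif suffix == ".gro":
        frames, boxes = _read_gro_frames(path, n_atoms)
        if isinstance(topology, System) and boxes and boxes[-1] is not None:
            topology.box = np.asarray(boxes[-1], dtype=float)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix}")
    return Trajectory(topology, frames, times=times)


# ---------------------------------------------------------------------------
# writers


def _iter_atoms(topology):
    if isinstance(topology, System):
        return list(topology.protein.atoms) + list(topology.surface.atoms)
    return list(topology.atoms)


def _pdb_atom_line(i: int, a: Atom, coord_nm: np.ndarray) -> str:
    x, y, z = coord_nm / A_TO_NM
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {min(i + 1, 99999):5d} {name:<4.4s} {a.res_name:<4.3s}"
        f"{a.chain_id:1.1s}{a.res_seq % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2.2s}"
    )


def write_structure(topology, path: str | Path) -> None:
    """Write a single-frame PDB/GRO/XYZ file for any atom group or system."""
    atoms = _iter_atoms(topology)
    coords = np.array([a.coord for a in atoms])
    _write_frames(topology, [coords], None, Path(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB, XYZ or GRO by extension."""
    _write_frames(traj.topology, traj.frames, traj.times, Path(path))


def _write_frames(topology, frames, times, path: Path) -> None:
    atoms = _iter_atoms(topology)
    suffix = path.suffix.lower()
    box = topology.box if isinstance(topology, System) and topology.box is not None \
        else None
    out: list[str] = []
    for k, frame in enumerate(frames):
        t = times[k] if times is not None else float(k)
        if suffix == ".pdb":
            out.append(f"MODEL     {k + 1:4d}")
            out.extend(_pdb_atom_line(i, a, c) for i, (a, c) in
                       enumerate(zip(atoms, frame)))
            out.append("ENDMDL")
        elif suffix == ".xyz":
            out.append(str(len(atoms)))
            out.append(f"frame {k} t= {t:.4f} ps")
            out.extend(
                f"{a.element:<3s} {c[0] / A_TO_NM:12.5f} {c[1] / A_TO_NM:12.5f} "
                f"{c[2] / A_TO_NM:12.5f}"
                for a, c in zip(atoms, frame)
            )
        elif suffix == ".gro":
            out.append(f"frame {k} t= {t:.4f}")
            out.append(f"{len(atoms):5d}")
            for i, (a, c) in enumerate(zip(atoms, frame)):
                out.append(
                    f"{a.res_seq % 100000:5d}{a.res_name:<5.5s}{a.name:>5.5s}"
                    f"{(i + 1) % 100000:5d}{c[0]:9.4f}{c[1]:9.4f}{c[2]:9.4f}"
                )
            b = box if box is not None else _bounding_box(frame)
            out.append(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}")
        else:
            raise ValueError(f"unsupported output format: {path.suffix}")
    if suffix == ".pdb":
        out.append("END")
    path.write_text("\n".join(out) + "\n")


def _bounding_box(frame: np.ndarray) -> np.ndarray:
    return frame.max(axis=0) - frame.min(axis=0) + 1.0


# ---------------------------------------------------------------------------
# report output


def _round_sig(x, sig: int = 6):
    if isinstance(x, bool) or not isinstance(x, (int, float)):
        return x
    if isinstance(x, int):
        return x
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def _round_tree(obj):
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v) for v in obj]
    return _round_sig(obj)


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Write an analysis report as JSON (sorted keys, 6 significant
    digits) or TSV (one header line plus one row per analyzed window).

    ``report`` may be a plain dict or any object with ``to_dict()``;
    TSV output additionally uses ``rows()`` when available.
    """
    path = Path(path)
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    if format == "json":
        path.write_text(json.dumps(_round_tree(data), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        rows = report.rows() if hasattr(report, "rows") else [_flatten(data)]
        keys = sorted({k for r in rows for k in r})
        lines = ["\t".join(keys)]
        for r in rows:
            lines.append("\t".join(_fmt(_round_sig(r.get(k, ""))) for k in keys))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = ",".join(str(_round_sig(x)) for x in v)
        else:
            out[key] = v
    return out
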