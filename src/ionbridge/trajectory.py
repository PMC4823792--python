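"""Trajectory containers and readers/writers (GRO, XYZ, internal CSV).

A :class:`Trajectory` holds an atom table (pandas DataFrame) shared by all
frames plus a ``(n_frames, n_atoms, 3)`` coordinate array in nm and a
per-frame orthorhombic box. The GRO dialect follows the GROMACS fixed-column
layout (positions in nm, 3 decimals); multiple concatenated models in one
file form a multi-frame trajectory. The internal CSV dialect is
``frame,atom_id,role,x,y,z`` (nm) with the box on a ``# box_nm=`` header
line. XYZ files are read with coordinates interpreted in nm and an optional
``box=Lx,Ly,Lz`` token on the comment line.

Only orthorhombic boxes are supported; GRO box lines carrying off-diagonal
(triclinic) components are rejected.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roles import AtomRole, assign_role

ATOM_COLUMNS = ["atom_id", "atom_name", "residue_name", "residue_number",
                "chain_id", "element", "role"]


class TrajectoryError(ValueError):
    """Malformed trajectory input (message carries the offending line)."""


@dataclass
class MolecularFrame:
    """One frame: the shared atom table plus this frame's coordinates."""

    atoms: pd.DataFrame
    coords: np.ndarray          # (n_atoms, 3) nm
    box: np.ndarray | None      # (3,) nm edge lengths, or None (no PBC)
    time_ps: float = 0.0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_of_role(self, role: AtomRole | str) -> np.ndarray:
        role = AtomRole(role)
        mask = (self.atoms["role"] == role.value).to_numpy()
        return self.coords[mask]

    def require_box(self) -> np.ndarray:
        if self.box is None:
            raise TrajectoryError("frame has no periodic box; required for this analysis")
        return self.box


@dataclass
class Trajectory:
    atoms: pd.DataFrame
    coords: np.ndarray                 # (n_frames, n_atoms, 3) nm
    box: np.ndarray | None             # (n_frames, 3) nm or None
    times_ps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.times_ps is None:
            self.times_ps = np.arange(self.n_frames, dtype=float)
        else:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.box is not None:
            self.box = np.atleast_2d(np.asarray(self.box, dtype=float))
            if self.box.shape[0] == 1 and self.n_frames > 1:
                self.box = np.repeat(self.box, self.n_frames, axis=0)
        if self.atoms["atom_id"].duplicated().any():
            raise TrajectoryError("atom_ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> MolecularFrame:
        box = None if self.box is None else self.box[i]
        return MolecularFrame(self.atoms, self.coords[i], box,
                              float(self.times_ps[i]))

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def indices_of_role(self, role: AtomRole | str) -> np.ndarray:
        role = AtomRole(role)
        return np.flatnonzero((self.atoms["role"] == role.value).to_numpy())

    def window(self, last_fraction: float | None = None,
               last_ps: float | None = None) -> "Trajectory":
        """Trailing analysis window, as a trailing fraction of frames
        (default 0.2) or a trailing span in ps."""
        if last_ps is not None:
            t_end = self.times_ps[-1]
            keep = self.times_ps > t_end - last_ps
        else:
            frac = 0.2 if last_fraction is None else float(last_fraction)
            if not 0 < frac <= 1:
                raise ValueError("last_fraction must be in (0, 1]")
            n_keep = max(1, int(round(frac * self.n_frames)))
            keep = np.zeros(self.n_frames, bool)
            keep[self.n_frames - n_keep:] = True
        if not keep.any():
            raise ValueError("analysis window is empty")
        box = None if self.box is None else self.box[keep]
        return Trajectory(self.atoms, self.coords[keep], box, self.times_ps[keep])


def _make_atoms(atom_ids, atom_names, residue_names, residue_numbers,
                chain_ids=None, elements=None, roles=None) -> pd.DataFrame:
    n = len(atom_ids)
    df = pd.DataFrame({
        "atom_id": np.asarray(atom_ids, dtype=int),
        "atom_name": list(atom_names),
        "residue_name": list(residue_names),
        "residue_number": np.asarray(residue_numbers, dtype=int),
        "chain_id": list(chain_ids) if chain_ids is not None else [""] * n,
        "element": list(elements) if elements is not None else [""] * n,
    })
    if roles is None:
        roles = _assign_roles(df)
    df["role"] = list(roles)
    return df


def _assign_roles(atoms: pd.DataFrame) -> list[str]:
    # a residue carrying OXT/OC1/OC2 exposes a terminal carboxylate
    terminal = set()
    for (rnum, rname), grp in atoms.groupby(["residue_number", "residue_name"]):
        names = {a.strip().upper() for a in grp["atom_name"]}
        if names & {"OXT", "OC1", "OC2"}:
            terminal.add((rnum, rname))
    return [
        assign_role(rn, an, (num, rn) in terminal).value
        for rn, an, num in zip(atoms["residue_name"], atoms["atom_name"],
                               atoms["residue_number"])
    ]


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    parts = line.split()
    if len(parts) < 3:
        raise TrajectoryError(f"line {lineno}: GRO box line needs >= 3 floats: {line!r}")
    vals = [float(p) for p in parts]
    if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise TrajectoryError(f"line {lineno}: triclinic GRO box not supported")
    box = np.array(vals[:3], dtype=float)
    if np.any(box <= 0):
        raise TrajectoryError(f"line {lineno}: GRO box edges must be positive")
    return box


def read_gro(path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, boxes, times = [], [], []
    atoms_df = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time_ps = 0.0
        if "t=" in title:
            try:
                time_ps = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            n_atoms = int(lines[i + 1].strip())
        except (ValueError, IndexError):
            raise TrajectoryError(f"line {i + 2}: expected atom count, got "
                                  f"{lines[i + 1]!r}" if i + 1 < len(lines)
                                  else f"line {i + 2}: truncated GRO file")
        first = i + 2
        last = first + n_atoms
        if last >= len(lines):
            raise TrajectoryError(f"line {len(lines)}: GRO file truncated "
                                  f"(expected {n_atoms} atoms plus box line)")
        ids, names, resnames, resnums, xyz = [], [], [], [], []
        for k in range(first, last):
            ln = lines[k]
            try:
                resnums.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                ids.append(int(ln[15:20]))
                xyz.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
            except (ValueError, IndexError):
                raise TrajectoryError(f"line {k + 1}: malformed GRO atom line: {ln!r}")
        box = _parse_gro_box(lines[last], last + 1)
        df = _make_atoms(ids, names, resnames, resnums)
        if atoms_df is None:
            atoms_df = df
        frames.append(np.array(xyz))
        boxes.append(box)
        times.append(time_ps)
        i = last + 1
    if atoms_df is None:
        raise TrajectoryError("empty GRO file")
    return Trajectory(atoms_df, np.stack(frames), np.stack(boxes),
                      np.array(times))


def write_gro(traj: Trajectory, path, title: str = "ionbridge") -> None:
    if traj.box is None:
        raise TrajectoryError("GRO output requires a periodic box")
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{title} t= {traj.times_ps[fi]:.3f}\n{traj.n_atoms:5d}\n")
            for a, (x, y, z) in zip(traj.atoms.itertuples(index=False),
                                    traj.coords[fi]):
                fh.write(f"{a.residue_number % 100000:5d}{a.residue_name:<5.5s}"
                         f"{a.atom_name:>5.5s}{a.atom_id % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = traj.box[fi]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# internal CSV dialect

def write_frames_csv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        if traj.box is not None:
            b = traj.box[0]
            fh.write(f"# box_nm={b[0]:.6f},{b[1]:.6f},{b[2]:.6f}\n")
        fh.write("frame,atom_id,role,x,y,z\n")
        for fi in range(traj.n_frames):
            for aid, role, (x, y, z) in zip(traj.atoms["atom_id"],
                                            traj.atoms["role"],
                                            traj.coords[fi]):
                fh.write(f"{fi},{aid},{role},{x:.6f},{y:.6f},{z:.6f}\n")


def read_frames_csv(path) -> Trajectory:
    box = None
    with open(path) as fh:
        head = fh.readline()
        while head.startswith("#"):
            if "box_nm=" in head:
                box = np.array([float(v) for v in
                                head.split("box_nm=")[1].strip().split(",")])
            head = fh.readline()
    df = pd.read_csv(path, comment="#")
    required = {"frame", "atom_id", "role", "x", "y", "z"}
    if not required <= set(df.columns):
        raise TrajectoryError(f"internal CSV missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise TrajectoryError("internal CSV contains no frames")
    frame_ids = np.sort(df["frame"].unique())
    first = df[df["frame"] == frame_ids[0]].sort_values("atom_id")
    atoms = _make_atoms(first["atom_id"], ["X"] * len(first), ["UNK"] * len(first),
                        np.zeros(len(first)), roles=list(first["role"]))
    coords = np.empty((len(frame_ids), len(first), 3))
    for j, fi in enumerate(frame_ids):
        sub = df[df["frame"] == fi].sort_values("atom_id")
        if len(sub) != len(first):
            raise TrajectoryError(f"frame {fi}: atom count differs from frame {frame_ids[0]}")
        coords[j] = sub[["x", "y", "z"]].to_numpy()
    boxes = None if box is None else np.repeat(box[None], len(frame_ids), axis=0)
    return Trajectory(atoms, coords, boxes, np.asarray(frame_ids, dtype=float))


# ---------------------------------------------------------------------------
# XYZ (coordinates in nm; optional "box=Lx,Ly,Lz" on the comment line)

def read_xyz(path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, boxes, elements = [], [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        if "box=" in comment:
            box = np.array([float(v) for v in
                            comment.split("box=")[1].split()[0].split(",")])
        elems, xyz = [], []
        for k in range(i + 2, i + 2 + n):
            if k >= len(lines):
                raise TrajectoryError(f"line {len(lines)}: XYZ file truncated")
            parts = lines[k].split()
            if len(parts) < 4:
                raise TrajectoryError(f"line {k + 1}: malformed XYZ atom line: {lines[k]!r}")
            elems.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = elems
        frames.append(np.array(xyz))
        boxes.append(box)
        i += 2 + n
    if elements is None:
        raise TrajectoryError("empty XYZ file")
    atoms = _make_atoms(np.arange(1, len(elements) + 1), elements,
                        ["UNK"] * len(elements), np.ones(len(elements)),
                        elements=elements)
    have_box = all(b is not None for b in boxes)
    return Trajectory(atoms, np.stack(frames),
                      np.stack(boxes) if have_box else None)


def read_frames(path, fmt: str | None = None) -> Trajectory:
    """Dispatching reader. ``fmt`` in {"gro", "xyz", "csv"}; inferred from
    the file extension when omitted."""
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    readers = {"gro": read_gro, "xyz": read_xyz, "csv": read_frames_csv}
    if fmt not in readers:
        raise ValueError(f"unknown trajectory format {fmt!r}; expected gro, xyz or csv")
    return readers[fmt](path)
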