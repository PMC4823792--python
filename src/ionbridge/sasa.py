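"""Shrake-Rupley solvent-accessible surface area.

Each atom's van der Waals sphere is inflated by the solvent probe radius
(default 0.14 nm, a water-sized probe) and covered with a deterministic
golden-section spiral of quasi-uniform test points. A point is accessible
if it lies outside every neighbouring atom's inflated sphere; the atom's
SASA is the accessible fraction of 4 pi (r + p)^2. Periodic neighbours are
included when the frame carries a box. Peptide oligomerization buries
surface, so the total SASA of a trajectory is a clustering readout: it
decreases as copies condense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import pairwise_min_image_distances
from .trajectory import MolecularFrame, Trajectory

#: Bondi van der Waals radii, nm. Override via ``radii_table``.
BONDI_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "F": 0.147, "CL": 0.175, "NA": 0.227, "CA": 0.231,
    "MG": 0.173, "K": 0.275, "ZN": 0.139,
}

PROBE_RADIUS_NM = 0.14


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere
    (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


_ION_RES_ELEMENTS = {"CA": "CA", "CAL": "CA", "CA2": "CA", "NA": "NA",
                     "SOD": "NA", "CL": "CL", "CLA": "CL", "MG": "MG",
                     "ZN": "ZN", "K": "K"}


def _element_of(atom_name: str, element: str, residue_name: str) -> str:
    """Element inference when the element field is empty: monatomic-ion
    residues map to their element; otherwise the first alphabetic character
    of the atom name (so CA the alpha carbon stays carbon)."""
    if element:
        return element.strip().upper()
    res = residue_name.strip().upper()
    if res in _ION_RES_ELEMENTS:
        return _ION_RES_ELEMENTS[res]
    stripped = atom_name.strip().upper().lstrip("0123456789")
    return stripped[0] if stripped else ""


def atom_radii(frame: MolecularFrame, radii_table=None) -> np.ndarray:
    table = dict(BONDI_RADII_NM)
    if radii_table:
        table.update({k.upper(): v for k, v in radii_table.items()})
    radii = np.empty(frame.n_atoms)
    missing = []
    for i, (name, elem, res) in enumerate(zip(frame.atoms["atom_name"],
                                              frame.atoms["element"],
                                              frame.atoms["residue_name"])):
        el = _element_of(name, elem, res)
        if el not in table:
            missing.append(f"{res}:{name}")
        else:
            radii[i] = table[el]
    if missing:
        raise ValueError("no van der Waals radius for atoms: " + ", ".join(missing))
    return radii


def shrake_rupley_sasa(frame: MolecularFrame, radii_table=None,
                       probe_radius_nm: float = PROBE_RADIUS_NM,
                       n_sphere_points: int = 960,
                       atom_subset: np.ndarray | None = None):
    """Per-atom and total SASA (nm^2) of one frame.

    ``atom_subset`` restricts both the reported atoms and the occluders
    (e.g. protein atoms only, excluding ions); periodic images are used as
    occluders whenever the frame has a box.
    """
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    idx = np.arange(frame.n_atoms) if atom_subset is None else np.asarray(atom_subset)
    sub = MolecularFrame(frame.atoms.iloc[idx].reset_index(drop=True),
                        frame.coords[idx], frame.box, frame.time_ps)
    radii = atom_radii(sub, radii_table) + probe_radius_nm
    coords = sub.coords
    n = len(idx)
    pts = sphere_points(n_sphere_points)
    areas = np.empty(n)
    rmax = radii.max()
    if frame.box is not None:
        box = frame.box
        tree = cKDTree(coords % box, boxsize=box)
    else:
        box = None
        tree = cKDTree(coords)
    for i in range(n):
        query = coords[i] % box if box is not None else coords[i]
        neigh = [j for j in tree.query_ball_point(query, radii[i] + rmax)
                 if j != i]
        test = coords[i] + radii[i] * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            delta = test - coords[j]
            if box is not None:
                delta = delta - box * np.round(delta / box)
            d2 = np.einsum("ij,ij->i", delta, delta)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


@dataclass
class SASATrace:
    times_ps: np.ndarray
    total_sasa_nm2: np.ndarray
    probe_radius_nm: float

    def window_stats(self, last_fraction: float | None = None,
                     last_ps: float | None = None):
        """Mean and s.e.m. of the total SASA over a trailing window of
        frames."""
        t = self.times_ps
        if last_ps is not None:
            if last_ps > t[-1] - t[0] + 1e-12 and len(t) > 1:
                raise ValueError("window longer than trace")
            keep = t > t[-1] - last_ps
        else:
            frac = 0.2 if last_fraction is None else float(last_fraction)
            n_keep = max(1, int(round(frac * len(t))))
            keep = np.zeros(len(t), bool)
            keep[len(t) - n_keep:] = True
        vals = self.total_sasa_nm2[keep]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return float(vals.mean()), sem

    def reaction_velocity(self, t0_ps: float, t1_ps: float) -> float:
        """Mean d(SASA)/dt (nm^2/ps) over [t0, t1], from the endpoints of a
        linear fit on the interval."""
        sel = (self.times_ps >= t0_ps) & (self.times_ps <= t1_ps)
        if sel.sum() < 2:
            raise ValueError("interval contains fewer than 2 frames")
        slope = np.polyfit(self.times_ps[sel], self.total_sasa_nm2[sel], 1)[0]
        return float(slope)


def sasa_trace(traj: Trajectory, radii_table=None,
               probe_radius_nm: float = PROBE_RADIUS_NM,
               n_sphere_points: int = 960,
               include_ions: bool = False) -> SASATrace:
    """Per-frame total SASA of the protein atoms (ions excluded as
    occluders unless ``include_ions``)."""
    ion_roles = {"calcium", "sodium", "chloride"}
    roles = traj.atoms["role"].to_numpy()
    subset = None
    if not include_ions:
        subset = np.flatnonzero(~np.isin(roles, list(ion_roles)))
        if subset.size == 0:
            raise ValueError("no non-ion atoms in trajectory")
    totals = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames()):
        _, totals[i] = shrake_rupley_sasa(frame, radii_table, probe_radius_nm,
                                          n_sphere_points, subset)
    return SASATrace(traj.times_ps.copy(), totals, probe_radius_nm)


def across_run_stats(window_means) -> tuple[float, float]:
    """Mean and s.e.m. across independent runs (n = number of runs)."""
    vals = np.asarray(list(window_means), dtype=float)
    if vals.size == 0:
        raise ValueError("no runs")
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), sem
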