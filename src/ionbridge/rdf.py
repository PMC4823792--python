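"""Radial distribution functions between atom-role groups.

g(r) is the density of role-b partners at distance r from a role-a atom,
relative to an ideal gas of the same mean density, averaged over frames.
Distances use the minimum-image convention; r_max must not exceed half the
smallest box edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import pairwise_min_image_distances
from .roles import AtomRole, DEFAULT_THRESHOLDS_NM
from .trajectory import Trajectory


@dataclass
class RDFResult:
    r_centers_nm: np.ndarray
    g_r: np.ndarray
    bin_width_nm: float
    n_frames: int
    density_b_per_nm3: float
    n_a: int
    n_b: int


def compute_rdf(traj: Trajectory, role_a: AtomRole | str, role_b: AtomRole | str,
                bin_width_nm: float = 0.002, r_max_nm: float = 1.0) -> RDFResult:
    """Frame-averaged g(r) between two role groups.

    Normalisation: pair-distance histogram divided by
    ``n_frames * n_a * shell_volume * rho_b`` with ``rho_b = n_b / V``
    (self-pairs excluded when the groups coincide).
    """
    ia = traj.indices_of_role(role_a)
    ib = traj.indices_of_role(role_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both role groups must be non-empty")
    if traj.box is None:
        raise ValueError("RDF requires a periodic box")
    box = traj.box
    if r_max_nm > box.min() / 2 + 1e-12:
        raise ValueError("r_max_nm exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max_nm + bin_width_nm, bin_width_nm)
    hist = np.zeros(len(edges) - 1)
    same_group = np.array_equal(ia, ib)
    vol = 0.0
    for fi in range(traj.n_frames):
        d = pairwise_min_image_distances(traj.coords[fi, ia],
                                         traj.coords[fi, ib], box[fi])
        if same_group:
            iu = np.triu_indices(len(ia), k=1)
            dvals = np.concatenate([d[iu], d[iu]])  # both directions
        else:
            dvals = d.ravel()
        hist += np.histogram(dvals, bins=edges)[0]
        vol += float(np.prod(box[fi]))
    vol /= traj.n_frames
    rho_b = len(ib) / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * len(ia) * shell * rho_b
    g = hist / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(centers, g, bin_width_nm, traj.n_frames, rho_b,
                     len(ia), len(ib))


def coordination_number(rdf: RDFResult, r_cut_nm: float) -> float:
    """Mean partner count within r_cut, integrating rho_b g(r) 4 pi r^2 dr."""
    sel = rdf.r_centers_nm <= r_cut_nm
    shell = 4 * np.pi * rdf.r_centers_nm[sel] ** 2 * rdf.bin_width_nm
    return float(np.sum(rdf.density_b_per_nm3 * rdf.g_r[sel] * shell))


def first_shell_threshold(rdf: RDFResult,
                          fallback_role: AtomRole | str | None = None,
                          fallback_nm: float | None = None,
                          smooth_bins: int = 3):
    """Contact threshold from the first minimum of g(r) after its first peak.

    g(r) is smoothed with a ``smooth_bins`` moving average; the first local
    minimum after the first peak exceeding 1 is returned. Featureless RDFs
    (no peak above 1, or no subsequent minimum) fall back to the role's
    default threshold with a warning. Returns ``(threshold_nm, from_rdf)``.
    """
    if fallback_nm is None:
        role = AtomRole(fallback_role) if fallback_role is not None else AtomRole.CARBOXYLATE_CARBON
        fallback_nm = DEFAULT_THRESHOLDS_NM.get(role, 0.4)
    g = rdf.g_r
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        g = np.convolve(g, kernel, mode="same")
    r = rdf.r_centers_nm
    peak_candidates = np.flatnonzero(g > 1.0)
    if peak_candidates.size == 0:
        warnings.warn("featureless RDF: no peak above 1; using fallback threshold")
        return float(fallback_nm), False
    # first local maximum above 1
    i = peak_candidates[0]
    while i + 1 < len(g) and g[i + 1] >= g[i]:
        i += 1
    # local minima after the peak; an inter-peak dip inside a bimodal first
    # shell stays above 1, the shell boundary falls below it, so prefer the
    # first minimum with g < 1 and otherwise take the deepest one
    minima = [k for k in range(i + 1, len(g) - 1)
              if g[k] <= g[k - 1] and g[k] <= g[k + 1]]
    if not minima:
        warnings.warn("RDF has no minimum after its first peak; using fallback threshold")
        return float(fallback_nm), False
    below = [k for k in minima if g[k] < 1.0]
    j = below[0] if below else min(minima, key=lambda k: g[k])
    return float(r[j]), True
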