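"""Ion-site contact detection and interaction stoichiometry.

A contact is an ion-site pair within a distance threshold (minimum image).
The stoichiometry spectrum groups contacts two ways, per frame:

* how many ions touch exactly i sites (i = 1..10) — one cation bridging
  several carboxylates is the clustering-competent motif,
* how many sites touch exactly i ions (i = 1..3) — multiply-occupied
  carboxylates signal saturation/overcharging.

Tallies are normalised by the number of analysed frames. Ions and sites
with zero contacts are excluded from the spectra but reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import pairwise_min_image_distances
from .roles import AtomRole
from .trajectory import MolecularFrame, Trajectory

MAX_ION_MULTIPLICITY = 10
MAX_SITE_MULTIPLICITY = 3


@dataclass
class StoichiometrySpectrum:
    ion_with_i_sites: dict = field(default_factory=dict)   # i -> mean per frame
    site_with_i_ions: dict = field(default_factory=dict)
    zero_contact_ions: float = 0.0
    zero_contact_sites: float = 0.0
    n_frames_analysed: int = 0
    n_ions: int = 0
    n_sites: int = 0
    window: str = ""


def contact_counts(frame: MolecularFrame,
                   ion_role: AtomRole | str = AtomRole.CALCIUM,
                   site_role: AtomRole | str = AtomRole.CARBOXYLATE_CARBON,
                   threshold_nm: float = 0.4):
    """Per-ion and per-site contact counts in one frame.

    Returns ``(ion_counts, site_counts)``; the two sum to the same number
    of contact pairs by construction.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    ions = frame.coords_of_role(ion_role)
    sites = frame.coords_of_role(site_role)
    if len(ions) == 0 or len(sites) == 0:
        return np.zeros(len(ions), dtype=int), np.zeros(len(sites), dtype=int)
    box = frame.require_box()
    d = pairwise_min_image_distances(ions, sites, box)
    contact = d < threshold_nm
    return contact.sum(axis=1), contact.sum(axis=0)


def stoichiometry_spectrum(traj: Trajectory,
                           last_fraction: float | None = None,
                           last_ps: float | None = None,
                           threshold_nm: float = 0.4,
                           ion_role: AtomRole | str = AtomRole.CALCIUM,
                           site_role: AtomRole | str = AtomRole.CARBOXYLATE_CARBON,
                           ) -> StoichiometrySpectrum:
    """Frame-normalised interaction stoichiometry over a trailing window."""
    win = traj.window(last_fraction=last_fraction, last_ps=last_ps) \
        if (last_fraction is not None or last_ps is not None) else traj
    ion_tally = np.zeros(MAX_ION_MULTIPLICITY + 1)
    site_tally = np.zeros(MAX_SITE_MULTIPLICITY + 1)
    zero_ions = zero_sites = 0
    n_ions = n_sites = 0
    for frame in win.frames():
        ic, sc = contact_counts(frame, ion_role, site_role, threshold_nm)
        n_ions, n_sites = len(ic), len(sc)
        zero_ions += int(np.sum(ic == 0))
        zero_sites += int(np.sum(sc == 0))
        for i in range(1, MAX_ION_MULTIPLICITY + 1):
            ion_tally[i] += int(np.sum(ic == i))
        for i in range(1, MAX_SITE_MULTIPLICITY + 1):
            site_tally[i] += int(np.sum(sc == i))
    nf = win.n_frames
    wdesc = (f"last_ps={last_ps}" if last_ps is not None
             else f"last_fraction={last_fraction}" if last_fraction is not None
             else "all frames")
    return StoichiometrySpectrum(
        ion_with_i_sites={i: ion_tally[i] / nf
                          for i in range(1, MAX_ION_MULTIPLICITY + 1)
                          if ion_tally[i] > 0},
        site_with_i_ions={i: site_tally[i] / nf
                          for i in range(1, MAX_SITE_MULTIPLICITY + 1)
                          if site_tally[i] > 0},
        zero_contact_ions=zero_ions / nf,
        zero_contact_sites=zero_sites / nf,
        n_frames_analysed=nf, n_ions=n_ions, n_sites=n_sites, window=wdesc,
    )


def bridging_frame_fraction(traj: Trajectory,
                            last_fraction: float | None = None,
                            last_ps: float | None = None,
                            threshold_nm: float = 0.4,
                            min_sites: int = 1,
                            ion_role: AtomRole | str = AtomRole.CALCIUM,
                            site_role: AtomRole | str = AtomRole.CARBOXYLATE_CARBON,
                            ) -> float:
    """Fraction of window frames in which *every* ion contacts at least
    ``min_sites`` sites (``min_sites=1``: all ions engaged in salt bridges;
    ``min_sites=2``: all ions bridging at least two carboxylates)."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    win = traj.window(last_fraction=last_fraction, last_ps=last_ps) \
        if (last_fraction is not None or last_ps is not None) else traj
    hits = 0
    for frame in win.frames():
        ic, _ = contact_counts(frame, ion_role, site_role, threshold_nm)
        if len(ic) and np.all(ic >= min_sites):
            hits += 1
    return hits / win.n_frames
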