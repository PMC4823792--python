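"""Seeded synthetic-data generators with known ground truth.

Three fixtures make every analysis stage testable without raw data:

* :func:`gen_sheet_image` — membrane-sheet-like micrographs: a uniform
  background, a diffuse signal component and Poisson-placed Gaussian
  clusters carrying a controllable share of the total signal, optionally
  blurred by a Gaussian PSF and corrupted by Gaussian or Poisson noise.
* :func:`gen_ideal_gas_frames` — i.i.d. uniform particle configurations in
  a periodic box, the calibration fixture for radial distribution
  functions (g(r) must be 1 everywhere).
* :func:`gen_bridged_frames` — trajectory frames in which each ion's number
  of carboxylate-site contacts is drawn from a prescribed distribution and
  realized exactly by construction, giving a known ground-truth
  stoichiometry spectrum.

All generators consume one ``numpy.random.default_rng(seed)`` per call and
are byte-reproducible for a fixed spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .geometry import pairwise_min_image_distances
from .roles import AtomRole
from .trajectory import Trajectory, _make_atoms


# ---------------------------------------------------------------------------
# membrane-sheet images

@dataclass
class ImageSpec:
    """Parameters of a synthetic membrane-sheet micrograph.

    ``signal_per_px`` is the mean specific signal per pixel (above
    background) before noise; ``clustered_fraction`` of it is carried by
    clusters, the rest is diffuse. Cluster centres are a Poisson point
    process with intensity ``cluster_density_per_um2``; profiles are 2-D
    Gaussians with sigma = ``cluster_radius_nm``, truncated at 3 sigma and
    normalised so each cluster injects an equal share of the clustered
    signal.
    """

    width_px: int = 128
    height_px: int = 128
    pixel_size_nm: float = 65.0
    cluster_density_per_um2: float = 4.0
    cluster_radius_nm: float = 80.0
    psf_sigma_nm: float = 0.0
    clustered_fraction: float = 0.3
    background_level: float = 20.0
    signal_per_px: float = 100.0
    noise_model: str = "none"      # none | gaussian | poisson
    noise_sigma: float = 0.0       # gaussian model only
    photon_gain: float = 1.0       # poisson model only
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_nm <= 0 or self.cluster_radius_nm <= 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.clustered_fraction <= 1:
            raise ValueError("clustered_fraction must be in [0, 1]")
        if self.background_level < 0 or self.signal_per_px < 0:
            raise ValueError("intensities must be non-negative")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        area_um2 = (self.width_px * self.height_px
                    * (self.pixel_size_nm / 1000.0) ** 2)
        if self.cluster_density_per_um2 * area_um2 > self.width_px * self.height_px:
            raise ValueError("cluster density exceeds one cluster per pixel")

    @property
    def area_um2(self) -> float:
        return (self.width_px * self.height_px
                * (self.pixel_size_nm / 1000.0) ** 2)


@dataclass
class SheetImageTruth:
    centers_px: np.ndarray          # (n, 2) as (row, col), float
    radii_nm: np.ndarray
    n_clusters: int
    clustered_signal: float         # realized, before noise
    total_signal: float             # realized specific signal, before noise
    clustered_fraction: float       # realized share


def _gaussian_spot(shape, center, sigma_px):
    """Unit-integral 2-D Gaussian truncated at 3 sigma, rendered in place."""
    h, w = shape
    r = int(np.ceil(3 * sigma_px))
    cy, cx = center
    y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))
    g[(yy - cy) ** 2 + (xx - cx) ** 2 > (3 * sigma_px) ** 2] = 0.0
    s = g.sum()
    if s == 0:
        return np.zeros(shape), 0.0
    g /= s
    img = np.zeros(shape)
    ys = np.clip(yy, 0, h - 1)
    xs = np.clip(xx, 0, w - 1)
    inside = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    np.add.at(img, (ys[inside], xs[inside]), g[inside])
    return img, float(g[inside].sum())


def gen_sheet_image(spec: ImageSpec):
    """Generate one synthetic sheet image.

    Returns ``(image, truth)`` where ``image`` is a float array (counts)
    and ``truth`` a :class:`SheetImageTruth` with the realized cluster
    centres and signal split. Before noise, the expected clustered share of
    the specific signal equals ``spec.clustered_fraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    n_px = h * w
    total_signal = spec.signal_per_px * n_px
    diffuse = (1.0 - spec.clustered_fraction) * total_signal / n_px
    img = np.full((h, w), float(spec.background_level) + diffuse)

    expected_n = spec.cluster_density_per_um2 * spec.area_um2
    n_clusters = int(rng.poisson(expected_n)) if expected_n > 0 else 0
    per_cluster = (spec.clustered_fraction * total_signal / expected_n
                   if expected_n > 0 else 0.0)
    centers = rng.uniform([0, 0], [h, w], size=(n_clusters, 2))
    sigma_px = spec.cluster_radius_nm / spec.pixel_size_nm
    clustered = 0.0
    for cy, cx in centers:
        spot, frac_inside = _gaussian_spot((h, w), (cy, cx), sigma_px)
        img += per_cluster * spot
        clustered += per_cluster * frac_inside

    if spec.psf_sigma_nm > 0:
        # wrap mode conserves total intensity exactly
        img = ndimage.gaussian_filter(img, spec.psf_sigma_nm / spec.pixel_size_nm,
                                      mode="wrap")

    realized_total = clustered + diffuse * n_px
    truth = SheetImageTruth(
        centers_px=centers, radii_nm=np.full(n_clusters, spec.cluster_radius_nm),
        n_clusters=n_clusters, clustered_signal=clustered,
        total_signal=realized_total,
        clustered_fraction=clustered / realized_total if realized_total > 0 else 0.0,
    )

    if spec.noise_model == "gaussian" and spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(img, 0.0, None)
    elif spec.noise_model == "poisson":
        g = spec.photon_gain
        img = rng.poisson(img * g).astype(float) / g
    return img, truth


# ---------------------------------------------------------------------------
# ideal-gas configurations

def gen_ideal_gas_frames(n_particles: int, box_nm, n_frames: int,
                         seed: int = 0) -> Trajectory:
    """Uncorrelated uniform configurations in a periodic box (RDF = 1)."""
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    box = np.asarray(box_nm, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box_nm must be 3 positive edge lengths")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_frames, n_particles, 3))
    atoms = _make_atoms(np.arange(1, n_particles + 1),
                        ["GAS"] * n_particles, ["GAS"] * n_particles,
                        np.arange(1, n_particles + 1),
                        roles=[AtomRole.OTHER.value] * n_particles)
    return Trajectory(atoms, coords, np.repeat(box[None], n_frames, axis=0))


# ---------------------------------------------------------------------------
# bridged ion/site frames

@dataclass
class BridgedFrameSpec:
    """Ground-truth generator for ion-site contact stoichiometry.

    Per frame and ion, a contact count i is drawn from
    ``contact_distribution`` (i -> probability, i in 0..10); exactly i sites
    are placed within ``contact_radius_nm`` of that ion and every other
    site lies beyond ``contact_radius_nm + placement_margin_nm`` of every
    ion (minimum-image distances).
    """

    n_ions: int = 3
    n_sites: int = 30
    contact_distribution: dict = field(default_factory=lambda: {1: 0.5, 3: 0.5})
    contact_radius_nm: float = 0.4
    placement_margin_nm: float = 0.2
    box_nm: tuple = (8.0, 8.0, 8.0)
    n_frames: int = 100
    seed: int = 0
    max_retries: int = 1000

    def validate(self) -> None:
        probs = np.array(list(self.contact_distribution.values()), dtype=float)
        keys = list(self.contact_distribution.keys())
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("contact_distribution probabilities must be >= 0 and sum to 1")
        if any(not 0 <= int(k) <= 10 for k in keys):
            raise ValueError("contact counts must lie in 0..10")
        box = np.asarray(self.box_nm, dtype=float)
        if self.contact_radius_nm + self.placement_margin_nm >= box.min() / 2:
            raise ValueError("contact_radius + margin must be below half the smallest box edge")
        if max(int(k) for k in keys) * self.n_ions > self.n_sites:
            raise ValueError("not enough sites to realize the largest contact count for all ions")


class PlacementError(RuntimeError):
    pass


def _place_frame(spec: BridgedFrameSpec, counts: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Place ions and sites realizing exactly the drawn per-ion counts."""
    box = np.asarray(spec.box_nm, dtype=float)
    r_in = spec.contact_radius_nm
    r_out = spec.contact_radius_nm + spec.placement_margin_nm
    for _ in range(spec.max_retries):
        # spread ions far apart so contact shells don't interact
        ions = rng.uniform(0, box, size=(spec.n_ions, 3))
        if spec.n_ions > 1:
            d = pairwise_min_image_distances(ions, ions, box)
            np.fill_diagonal(d, np.inf)
            if d.min() < 2 * r_out:
                continue
        sites = []
        ok = True
        for i, c in enumerate(counts):
            for _ in range(int(c)):
                # uniform in the contact ball of ion i
                vec = rng.normal(size=3)
                vec *= (r_in * 0.9) * rng.uniform() ** (1 / 3) / np.linalg.norm(vec)
                sites.append((ions[i] + vec) % box)
        n_far = spec.n_sites - int(counts.sum())
        placed_far = 0
        attempts = 0
        while placed_far < n_far and attempts < 100 * max(n_far, 1):
            cand = rng.uniform(0, box, size=3)
            if pairwise_min_image_distances(cand[None], ions, box).min() > r_out:
                sites.append(cand)
                placed_far += 1
            attempts += 1
        if placed_far < n_far:
            ok = False
        if ok:
            return ions, np.array(sites)
    raise PlacementError("placement failed after retries")


def gen_bridged_frames(spec: BridgedFrameSpec):
    """Generate a trajectory with known ion-site contact stoichiometry.

    Returns ``(trajectory, ground_truth)``. Ground truth is the *realized*
    spectrum: mean number of ions with exactly i contacts per frame
    (i = 1..10), plus the mean zero-contact ion count, as a dict
    ``{"ion_with_i_sites": {i: freq}, "zero_contact_ions": float, ...}``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ks = np.array([int(k) for k in spec.contact_distribution.keys()])
    ps = np.array([float(v) for v in spec.contact_distribution.values()])
    ps = ps / ps.sum()

    all_coords = []
    tallies = np.zeros(11)
    drawn_counts = np.zeros((spec.n_frames, spec.n_ions), dtype=int)
    for f in range(spec.n_frames):
        counts = rng.choice(ks, size=spec.n_ions, p=ps)
        drawn_counts[f] = counts
        try:
            ions, sites = _place_frame(spec, counts, rng)
        except PlacementError as e:
            raise PlacementError(f"frame {f}: {e}") from None
        all_coords.append(np.vstack([ions, sites]))
        for c in counts:
            tallies[int(c)] += 1

    n_atoms = spec.n_ions + spec.n_sites
    roles = ([AtomRole.CALCIUM.value] * spec.n_ions
             + [AtomRole.CARBOXYLATE_CARBON.value] * spec.n_sites)
    atoms = _make_atoms(np.arange(1, n_atoms + 1),
                        ["CA"] * spec.n_ions + ["CG"] * spec.n_sites,
                        ["CA"] * spec.n_ions + ["ASP"] * spec.n_sites,
                        np.arange(1, n_atoms + 1), roles=roles)
    box = np.repeat(np.asarray(spec.box_nm, dtype=float)[None],
                    spec.n_frames, axis=0)
    traj = Trajectory(atoms, np.stack(all_coords), box)
    truth = {
        "ion_with_i_sites": {i: tallies[i] / spec.n_frames for i in range(1, 11)
                             if tallies[i] > 0},
        "zero_contact_ions": tallies[0] / spec.n_frames,
        "drawn_counts": drawn_counts,
        "n_frames": spec.n_frames,
    }
    return traj, truth


def save_image(path_tiff, image: np.ndarray, spec: ImageSpec,
               truth: SheetImageTruth | None = None) -> None:
    """Write a 16-bit TIFF plus a JSON sidecar with spec and ground truth."""
    import tifffile

    arr = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path_tiff, arr)
    side = {"spec": asdict(spec)}
    if truth is not None:
        side["truth"] = {
            "centers_px": truth.centers_px.tolist(),
            "radii_nm": truth.radii_nm.tolist(),
            "n_clusters": truth.n_clusters,
            "clustered_signal": truth.clustered_signal,
            "total_signal": truth.total_signal,
            "clustered_fraction": truth.clustered_fraction,
        }
    with open(str(path_tiff) + ".json", "w") as fh:
        json.dump(side, fh, indent=1)
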