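"""Quantification of protein clustering in membrane-sheet micrographs.

The readouts mirror a standard epifluorescence/STED workflow:

* background-corrected mean intensity of a region of interest (ROI),
* the relative standard deviation (coefficient of variation) of the
  background-corrected ROI — a segmentation-free clustering metric that is
  zero for a perfectly uniform stain and grows as signal concentrates into
  microdomains,
* cluster counting with ImageJ-style "find maxima" prominence semantics
  and conversion to a density per um^2,
* a pixel-shift Pearson autocorrelation curve whose 50%-decay shift,
  extracted from a polynomial fit, estimates the mean object radius,
* the fraction of signal inside punctate (above mean + k*SD) areas.

Pixel coordinates are 0-based with the origin at the top-left; areas are
width x height x pixel_size^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SheetImage:
    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


@dataclass
class ROI:
    x0: int
    y0: int
    width: int
    height: int

    def validate(self, image: SheetImage) -> None:
        h, w = image.pixels.shape
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI must be non-empty")
        if not (0 <= self.x0 and 0 <= self.y0
                and self.x0 + self.width <= w and self.y0 + self.height <= h):
            raise ValueError("ROI extends outside the image")

    def extract(self, image: SheetImage) -> np.ndarray:
        self.validate(image)
        return image.pixels[self.y0:self.y0 + self.height,
                            self.x0:self.x0 + self.width]

    def area_um2(self, image: SheetImage) -> float:
        return self.width * self.height * (image.pixel_size_nm / 1000.0) ** 2


@dataclass
class AutocorrCurve:
    shifts_px: np.ndarray
    pcc: np.ndarray             # NaN marks shifts with undefined PCC
    pixel_size_nm: float


@dataclass
class ClusterMetrics:
    mean_intensity_bgcorr: float = np.nan
    rel_sd: float = np.nan
    rel_sd_normalized: float = np.nan
    cluster_density_per_um2: float = np.nan
    cluster_radius_nm: float = np.nan
    clustered_fraction: float = np.nan


def background_corrected_mean(image: SheetImage, roi: ROI,
                              background_roi: ROI) -> float:
    """Mean ROI intensity minus the mean of a background ROI placed next to
    the sheet. A negative result is returned as-is (it flags a bad ROI)."""
    return float(roi.extract(image).mean() - background_roi.extract(image).mean())


def relative_sd(image: SheetImage, roi: ROI, background: float = 0.0) -> float:
    """Coefficient of variation of background-corrected ROI intensities.

    Zero for a perfectly uniform region; increases as fluorescence
    accumulates in clusters. Undefined (raises) when the corrected mean is
    not positive.
    """
    px = roi.extract(image) - background
    mean = px.mean()
    if mean <= 0:
        raise ValueError("relative SD undefined: background-corrected mean is not positive")
    return float(px.std(ddof=0) / mean)


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide each value by the mean of the control (baseline) set."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control set is empty")
    m = control.mean()
    if m <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / m


# ---------------------------------------------------------------------------
# find maxima

def _regional_maxima(img: np.ndarray):
    """Connected equal-value plateaus (8-connectivity) with no higher
    neighbour and at least one strictly lower neighbour."""
    from scipy import ndimage

    h, w = img.shape
    # plateau labelling among equal-valued neighbours
    visited = np.zeros((h, w), dtype=bool)
    maxima = []
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            v = img[sy, sx]
            stack = [(sy, sx)]
            visited[sy, sx] = True
            plateau = []
            is_max = True
            has_lower = False
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        ny, nx = y + dy, x + dx
                        if not (0 <= ny < h and 0 <= nx < w):
                            continue
                        nv = img[ny, nx]
                        if nv > v:
                            is_max = False
                        elif nv < v:
                            has_lower = True
                        elif not visited[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            if is_max and has_lower:
                maxima.append((v, plateau))
    return maxima


def find_maxima(img: np.ndarray, noise_level: float):
    """ImageJ-style "find maxima": a maximum counts if it cannot be reached
    from higher terrain without descending more than ``noise_level``.

    From each candidate maximum (value v, processed in descending order) the
    connected region of pixels with value strictly above ``v - noise_level``
    is flooded; if the flood meets a higher pixel the candidate is absorbed,
    and any lower maxima inside the flood are absorbed by it. Counted
    maxima are returned as plateau centroids (row, col).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    maxima = sorted(_regional_maxima(img), key=lambda m: -m[0])
    absorbed = np.zeros((h, w), dtype=bool)
    out = []
    for v, plateau in maxima:
        if absorbed[plateau[0]]:
            continue
        # flood pixels with value > v - noise_level
        seen = np.zeros((h, w), dtype=bool)
        stack = list(plateau)
        for p in plateau:
            seen[p] = True
        reached_higher = False
        flood = []
        while stack:
            y, x = stack.pop()
            flood.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or seen[ny, nx]:
                        continue
                    nv = img[ny, nx]
                    if nv > v:
                        reached_higher = True
                    elif nv > v - noise_level:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
        for p in flood:
            absorbed[p] = True
        if not reached_higher:
            ys = np.array([p[0] for p in plateau], dtype=float)
            xs = np.array([p[1] for p in plateau], dtype=float)
            out.append((ys.mean(), xs.mean()))
    return out


def detect_clusters(image: SheetImage, roi: ROI, noise_level: float):
    """Count clusters in the ROI via :func:`find_maxima` and report
    ``(maxima_coords, density_per_um2)``; coordinates are ROI-local."""
    sub = roi.extract(image)
    maxima = find_maxima(sub, noise_level)
    density = len(maxima) / roi.area_um2(image)
    return maxima, density


# ---------------------------------------------------------------------------
# autocorrelation

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def autocorr_curve(image: SheetImage, roi: ROI, max_shift_px: int,
                   isotropic: bool = False) -> AutocorrCurve:
    """Pixel-shift Pearson autocorrelation of the ROI.

    For each shift the ROI is compared with a copy translated rightward
    (``isotropic=True`` averages the four axis directions), using only the
    overlapping region — no wraparound. Zero-variance overlaps yield NaN.
    """
    if max_shift_px >= roi.width:
        raise ValueError("max_shift_px must be smaller than the ROI width")
    sub = roi.extract(image)
    shifts = np.arange(max_shift_px + 1)
    pcc = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        if s == 0:
            pcc[i] = 1.0 if sub.std() > 0 else np.nan
            continue
        vals = [_pearson(sub[:, s:], sub[:, :-s])]
        if isotropic:
            # horizontal and vertical shifts; PCC is symmetric under shift
            # sign, so two axes cover all four directions
            vals.append(_pearson(sub[s:, :], sub[:-s, :]))
        vals = [v for v in vals if not np.isnan(v)]
        pcc[i] = np.mean(vals) if vals else np.nan
    return AutocorrCurve(shifts, pcc, image.pixel_size_nm)


def average_curves(curves) -> AutocorrCurve:
    """Pointwise mean of autocorrelation curves on identical shift grids;
    missing (NaN) values are excluded pointwise."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    shifts = curves[0].shifts_px
    for c in curves[1:]:
        if not np.array_equal(c.shifts_px, shifts):
            raise ValueError("curves have different shift grids")
    stacked = np.vstack([c.pcc for c in curves])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return AutocorrCurve(shifts, mean, curves[0].pixel_size_nm)


def radius_from_autocorr(curve: AutocorrCurve, poly_order: int = 4) -> float:
    """Object radius (nm) from the 50% decay of a polynomial fit.

    The PCC-vs-shift curve is least-squares fitted with a polynomial; the
    half-decay shift is where the fit first crosses the midpoint between
    its value at shift 0 and its baseline (the fitted value at the largest
    shift). Radius = half-decay shift x pixel size.
    """
    good = ~np.isnan(curve.pcc)
    shifts = curve.shifts_px[good].astype(float)
    pcc = curve.pcc[good]
    if len(shifts) < poly_order + 2:
        raise ValueError("curve has too few points for the requested polynomial order")
    coeffs = np.polyfit(shifts, pcc, poly_order)
    poly = np.poly1d(coeffs)
    baseline = poly(shifts[-1])
    level = 0.5 * (poly(shifts[0]) + baseline)
    grid = np.linspace(shifts[0], shifts[-1], 4096)
    vals = poly(grid)
    below = np.flatnonzero(vals <= level)
    if below.size == 0 or below[0] == 0:
        raise ValueError("fitted autocorrelation never decays through the 50% level")
    i = below[0]
    # linear interpolation between bracketing grid points
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = vals[i - 1], vals[i]
    half_shift = x0 + (level - y0) * (x1 - x0) / (y1 - y0)
    return float(half_shift * curve.pixel_size_nm)


def expected_half_decay_radius(sigma_nm: float) -> float:
    """50%-decay radius of the autocorrelation of a Gaussian object of
    width sigma: the image autocorrelation is Gaussian with width
    sigma*sqrt(2), so the half-decay shift is 2*sqrt(ln 2)*sigma. This is
    the quantity :func:`radius_from_autocorr` estimates for Gaussian
    clusters."""
    return 2.0 * np.sqrt(np.log(2.0)) * sigma_nm


def clustered_fraction(image: SheetImage, roi: ROI, k_sigma: float = 2.0,
                       background: float = 0.0) -> float:
    """Share of (background-corrected) ROI signal inside punctate areas,
    segmented as pixels above mean + k_sigma * SD of the ROI."""
    px = roi.extract(image) - background
    total = px.sum()
    if total <= 0:
        raise ValueError("total ROI signal must be positive")
    thresh = px.mean() + k_sigma * px.std(ddof=0)
    mask = px > thresh
    return float(px[mask].sum() / total)
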