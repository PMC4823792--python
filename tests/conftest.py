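import numpy as np
import pytest

from ionbridge.imaging import ROI, SheetImage
from ionbridge.synthetic import BridgedFrameSpec, ImageSpec, gen_sheet_image


@pytest.fixture(scope="session")
def spot_image():
    """One well-separated Gaussian-spot field with its ground truth."""
    spec = ImageSpec(width_px=96, height_px=96, pixel_size_nm=65.0,
                     cluster_density_per_um2=1.0, cluster_radius_nm=80.0,
                     clustered_fraction=0.5, seed=7)
    img, truth = gen_sheet_image(spec)
    return SheetImage(img, spec.pixel_size_nm), spec, truth


@pytest.fixture(scope="session")
def bridged_fixture():
    """Deterministic mixed-stoichiometry trajectory with ground truth."""
    from ionbridge.synthetic import gen_bridged_frames

    spec = BridgedFrameSpec(n_ions=3, n_sites=30,
                            contact_distribution={1: 0.5, 3: 0.5},
                            n_frames=120, seed=11)
    traj, truth = gen_bridged_frames(spec)
    return traj, truth, spec


@pytest.fixture
def full_roi():
    def _make(image: SheetImage) -> ROI:
        h, w = image.pixels.shape
        return ROI(0, 0, w, h)
    return _make


def brute_force_maxima(img: np.ndarray, noise_level: float):
    """Independent prominence search: for every strict regional-maximum
    plateau, BFS over pixels with value > v - noise_level; the plateau
    counts only if the flood never reaches higher terrain and no
    already-counted (higher) maximum lies inside the flood."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape

    def neighbors(y, x):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy or dx) and 0 <= y + dy < h and 0 <= x + dx < w:
                    yield y + dy, x + dx

    # regional maxima plateaus
    seen = np.zeros((h, w), bool)
    plateaus = []
    for y in range(h):
        for x in range(w):
            if seen[y, x]:
                continue
            v = img[y, x]
            comp, stack = [], [(y, x)]
            seen[y, x] = True
            is_max, has_lower = True, False
            while stack:
                cy, cx = stack.pop()
                comp.append((cy, cx))
                for ny, nx in neighbors(cy, cx):
                    if img[ny, nx] > v:
                        is_max = False
                    elif img[ny, nx] < v:
                        has_lower = True
                    elif not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            if is_max and has_lower:
                plateaus.append((v, comp))
    plateaus.sort(key=lambda p: -p[0])
    counted = []
    absorbed = set()
    for v, comp in plateaus:
        if comp[0] in absorbed:
            continue
        flood = set(comp)
        stack = list(comp)
        higher = False
        while stack:
            cy, cx = stack.pop()
            for ny, nx in neighbors(cy, cx):
                if (ny, nx) in flood:
                    continue
                if img[ny, nx] > v:
                    higher = True
                elif img[ny, nx] > v - noise_level:
                    flood.add((ny, nx))
                    stack.append((ny, nx))
        absorbed |= flood
        if not higher:
            counted.append(comp)
    return counted
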