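"""Periodic geometry for orthorhombic boxes.

All distance operations in the package go through the minimum-image
convention implemented here. Boxes are orthorhombic edge-length vectors in
nm; triclinic boxes are rejected at the IO layer.
"""

from __future__ import annotations

import numpy as np


def wrap_deltas(deltas: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap Cartesian displacement(s) into [-L/2, L/2) per axis."""
    box = np.asarray(box, dtype=float)
    return deltas - box * np.round(deltas / box)


def minimum_image_distance(a, b, box) -> float:
    """Euclidean distance between points ``a`` and ``b`` (nm) under the
    minimum-image convention in an orthorhombic box of edge lengths ``box``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = wrap_deltas(a - b, box)
    return float(np.sqrt(np.sum(d * d, axis=-1)))


def pairwise_min_image_distances(xa: np.ndarray, xb: np.ndarray, box) -> np.ndarray:
    """(len(xa), len(xb)) matrix of minimum-image distances in nm."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    box = np.asarray(box, dtype=float)
    d = xa[:, None, :] - xb[None, :, :]
    d = wrap_deltas(d, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))
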