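"""Periodic-boundary geometry.

The analysis model treats the membrane plane (x, y) as periodic and the
membrane normal (z) as open: minimum-image wrapping is applied laterally only.
Boxes are orthorhombic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import GeometryError


def wrap_xy(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap x,y into [0, Lx) x [0, Ly); z untouched."""
    out = np.array(coords, dtype=float, copy=True)
    out[..., 0] %= box[0]
    out[..., 1] %= box[1]
    return out


def min_image_vec(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a, periodic in x/y, direct in z.

    Broadcasts over leading dimensions.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise GeometryError(f"box lengths must be positive, got {box}")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = np.array(d, copy=True)
    for k in (0, 1):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Euclidean distance under the lateral minimum-image convention."""
    d = min_image_vec(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def lateral_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """xy-plane minimum-image distance (ignores z)."""
    d = min_image_vec(a, b, box)
    return np.hypot(d[..., 0], d[..., 1])


def _lifted_tree(coords: np.ndarray, box: np.ndarray, r_max: float,
                 z_shift: float, z_period: float) -> cKDTree:
    pts = np.empty_like(coords)
    pts[:, 0] = coords[:, 0] % box[0]
    pts[:, 1] = coords[:, 1] % box[1]
    pts[:, 2] = coords[:, 2] + z_shift
    return cKDTree(pts, boxsize=[box[0], box[1], z_period])

def neighbor_pairs(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                   r_max: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All pairs (i, j) with ``min_image_dist(a[i], b[j]) <= r_max``.

    Uses a kd-tree with a z period chosen large enough that the non-periodic
    z axis can never wrap within ``r_max``; exact distances are then
    recomputed with :func:`min_image_dist` so boundary behaviour matches the
    brute-force definition.

    Returns (i_idx, j_idx, dist) arrays.
    """
    if min(box[0], box[1]) < 2 * r_max:
        raise GeometryError(
            f"r_max={r_max} exceeds half the smallest lateral box length "
            f"({min(box[0], box[1]) / 2:g} nm)"
        )
    z_all = np.concatenate([a[:, 2], b[:, 2]])
    z_min, z_max = float(z_all.min()), float(z_all.max())
    z_shift = -z_min + 2 * r_max
    z_period = (z_max - z_min) + 4 * r_max
    ta = _lifted_tree(a, box, r_max, z_shift, z_period)
    tb = _lifted_tree(b, box, r_max, z_shift, z_period)
    hits = ta.query_ball_tree(tb, r_max)
    i_idx = np.concatenate(
        [np.full(len(js), i, dtype=np.int64) for i, js in enumerate(hits)]
    ) if any(hits) else np.empty(0, dtype=np.int64)
    j_idx = (np.concatenate([np.asarray(js, dtype=np.int64) for js in hits if js])
             if any(hits) else np.empty(0, dtype=np.int64))
    if len(i_idx) == 0:
        return i_idx, j_idx, np.empty(0, dtype=float)
    dist = min_image_dist(a[i_idx], b[j_idx], box)
    keep = dist <= r_max
    return i_idx[keep], j_idx[keep], dist[keep]


def neighbor_counts_xy(points: np.ndarray, box: np.ndarray,
                       radius: float) -> list[list[int]]:
    """For each 2D point, indices of points within lateral ``radius`` (periodic).

    Includes the point itself.
    """
    pts = np.empty_like(points[:, :2])
    pts[:, 0] = points[:, 0] % box[0]
    pts[:, 1] = points[:, 1] % box[1]
    tree = cKDTree(pts, boxsize=[box[0], box[1]])
    return tree.query_ball_point(pts, radius)
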