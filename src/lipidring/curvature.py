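"""Membrane height fields and ring-referenced depression depth.

The height field is the per-cell mean phosphate z of one leaflet over a
frame window, on the same lateral grid as the density maps (default 0.5 nm
cells).  The height-change map subtracts the *initial* from the *final*
window field on the intersection of their occupancy masks, visualising the
membrane moving from its flat starting state to the invaginated end state.

Depression depth is referenced to the final far field so any global z drift
cancels: reference = mean final height over cells farther than 1.5x the ring
radius from the ring centre; in-ring statistics are taken over the central
disk (half the ring radius).  Both the mean-based depth and the peak
(minimum-cell) depth are reported, since a quoted depression range can
plausibly span mean-to-peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import (
    CoverageError,
    EmptySelectionError,
    GeometryError,
    Trajectory,
    WindowError,
)
from .leaflets import LeafletAssignment
from .enrichment import RingRegion
from .density import grid_shape


@dataclass
class HeightField:
    mean_z: np.ndarray        # (nx, ny) nm, valid only where mask
    mask: np.ndarray          # (nx, ny) bool, cells with >= 1 bead
    cell: float
    window: tuple[int, int]
    leaflet: str
    box: tuple[float, float]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.mean_z.shape
        cx = (np.arange(nx) + 0.5) * self.cell
        cy = (np.arange(ny) + 0.5) * self.cell
        return np.meshgrid(cx, cy, indexing="ij")

    def to_csv(self, path: str | Path) -> None:
        out = np.where(self.mask, self.mean_z, np.nan)
        np.savetxt(path, out, delimiter=",", fmt="%.8g")


@dataclass
class DepressionResult:
    reference_height: float   # nm, final far-field mean
    in_ring_mean: float       # nm
    in_ring_min: float        # nm
    depth: float              # nm, reference - in_ring_mean
    depth_min: float          # nm, reference - in_ring_min

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def height_field(
    traj: Trajectory,
    leaflets: LeafletAssignment,
    window: tuple[int, int],
    leaflet: str = "upper",
    cell: float = 0.5,
    smooth: bool = False,
) -> HeightField:
    """Per-cell mean phosphate z of one leaflet over the window frames."""
    lo, hi = window
    if not (0 <= lo < hi <= traj.n_frames):
        raise WindowError(f"window {window} invalid for "
                          f"{traj.n_frames}-frame trajectory")
    topo = traj.topology
    lt = topo.lipid_table()
    bead_ids = lt.all_phosphates
    cols = np.searchsorted(leaflets.molecule_ids, topo.molecule_id[bead_ids])
    nx, ny = grid_shape(traj.box, cell)
    zsum = np.zeros((nx, ny))
    nsum = np.zeros((nx, ny))
    got_any = False
    for f in range(lo, hi):
        active = bead_ids[leaflets.labels[f, cols] == leaflet]
        if len(active) == 0:
            continue
        got_any = True
        xyz = traj.xyz[f, active]
        ix = np.floor(xyz[:, 0] % traj.box[0] / cell).astype(np.int64) % nx
        iy = np.floor(xyz[:, 1] % traj.box[1] / cell).astype(np.int64) % ny
        np.add.at(zsum, (ix, iy), xyz[:, 2])
        np.add.at(nsum, (ix, iy), 1.0)
    if not got_any:
        raise EmptySelectionError(
            f"no phosphate beads on leaflet {leaflet!r} in window {window}")
    mask = nsum > 0
    mean_z = np.zeros((nx, ny))
    mean_z[mask] = zsum[mask] / nsum[mask]
    field = HeightField(mean_z=mean_z, mask=mask, cell=cell, window=window,
                        leaflet=leaflet, box=(float(traj.box[0]),
                                              float(traj.box[1])))
    return _smooth_field(field) if smooth else field


def _smooth_field(field: HeightField) -> HeightField:
    """Mask-aware 3x3 mean filter with periodic lateral wrap."""
    z = np.where(field.mask, field.mean_z, 0.0)
    m = field.mask.astype(float)
    zacc = np.zeros_like(z)
    macc = np.zeros_like(m)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            zacc += np.roll(np.roll(z, dx, axis=0), dy, axis=1)
            macc += np.roll(np.roll(m, dx, axis=0), dy, axis=1)
    mask = macc > 0
    out = np.zeros_like(z)
    out[mask] = zacc[mask] / macc[mask]
    return HeightField(mean_z=out, mask=mask, cell=field.cell,
                       window=field.window, leaflet=field.leaflet,
                       box=field.box)


def height_change_map(
    traj: Trajectory,
    leaflets: LeafletAssignment,
    leaflet: str = "upper",
    cell: float = 0.5,
    windows: dict[str, tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(final - initial) height difference on the intersection of masks.

    Returns ``(delta, mask)``; cells outside the mask are NaN in ``delta``.
    """
    from .density import window_presets

    windows = windows or window_presets(traj)
    initial = height_field(traj, leaflets, windows["initial"], leaflet, cell)
    final = height_field(traj, leaflets, windows["final"], leaflet, cell)
    mask = initial.mask & final.mask
    if not np.any(mask):
        raise CoverageError("initial and final height fields share no "
                            "occupied cells")
    delta = np.full(initial.mean_z.shape, np.nan)
    delta[mask] = final.mean_z[mask] - initial.mean_z[mask]
    return delta, mask


def _cell_distances(field: HeightField, region: RingRegion) -> np.ndarray:
    cx, cy = field.cell_centers()
    dx = cx - region.center[0]
    dy = cy - region.center[1]
    # periodic lateral distance
    dx -= field.box[0] * np.round(dx / field.box[0])
    dy -= field.box[1] * np.round(dy / field.box[1])
    return np.hypot(dx, dy)


def depression_depth(
    field_initial: HeightField,
    field_final: HeightField,
    region: RingRegion,
    far_factor: float = 1.5,
    inner_factor: float = 0.5,
) -> DepressionResult:
    """Ring-referenced depression statistics of the final height field.

    ``field_initial`` is accepted for interface symmetry and mask
    cross-checking; the depth itself is defined entirely on the final field
    (far-field reference minus central-disk statistics) so that global z
    drift between the windows cancels.
    """
    if field_initial.mean_z.shape != field_final.mean_z.shape:
        raise GeometryError("height fields must share the same grid")
    d = _cell_distances(field_final, region)
    far = field_final.mask & (d > far_factor * region.radius)
    inner = field_final.mask & (d <= inner_factor * region.radius)
    if not np.any(far):
        raise GeometryError(
            f"no occupied far-field cells beyond {far_factor:g}x ring radius")
    if not np.any(inner):
        raise GeometryError(
            f"no occupied cells within {inner_factor:g}x ring radius")
    reference = float(np.mean(field_final.mean_z[far]))
    in_mean = float(np.mean(field_final.mean_z[inner]))
    in_min = float(np.min(field_final.mean_z[inner]))
    return DepressionResult(
        reference_height=reference,
        in_ring_mean=in_mean,
        in_ring_min=in_min,
        depth=reference - in_mean,
        depth_min=reference - in_min,
    )
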