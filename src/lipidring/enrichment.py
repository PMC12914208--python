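"""Ring-region definition, temporal lipid counts, and enrichment ratios.

The *ring region* is the lateral disk enclosed by the protein ring.  Its
centre and radius are obtained by an algebraic (Kasa) least-squares circle
fit to the xy projection of the protein beads; a margin can widen the disk.

Per frame, per species and per leaflet, the number of lipid molecules whose
first phosphate bead lies laterally (periodic xy) inside the region is
counted — the machine-readable version of the temporal in-ring lipid-count
traces.  The enrichment ratio compares in-region areal density with the
leaflet-wide areal density:

    ratio = (in-region count / region area) / (leaflet species total / box area)

so uniform placement gives 1 in expectation and cardiolipin sorting toward
the ring drives the CL ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BeadTopology,
    Frame,
    GeometryError,
    RingFitError,
    Trajectory,
    UndefinedRatioError,
)
from .geometry import lateral_dist
from .leaflets import LeafletAssignment


@dataclass
class RingRegion:
    center: tuple[float, float]
    radius: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def effective_radius(self) -> float:
        return self.radius + self.margin

    @property
    def area(self) -> float:
        return float(np.pi * self.effective_radius**2)


def fit_ring_region(topology: BeadTopology, frame: Frame,
                    margin: float = 0.0) -> RingRegion:
    """Least-squares (Kasa) circle fit to the xy positions of protein beads.

    Solves ``[2x 2y 1] [a b c]' = x^2 + y^2`` for centre (a, b) and radius
    ``sqrt(c + a^2 + b^2)``.  Assumes the ring does not wrap across the
    periodic boundary (the generator places it at the box centre).
    """
    xy = frame.coords[topology.is_protein, :2]
    if xy.shape[0] < 3:
        raise RingFitError(f"circle fit needs >= 3 protein beads, got "
                           f"{xy.shape[0]}")
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    # collinear points make A rank-deficient
    if np.linalg.matrix_rank(A, tol=1e-9) < 3:
        raise RingFitError("protein bead positions are collinear or degenerate")
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    a, b, c = sol
    r2 = c + a**2 + b**2
    if r2 <= 0:
        raise RingFitError("degenerate circle fit (non-positive radius)")
    return RingRegion(center=(float(a), float(b)), radius=float(np.sqrt(r2)),
                      margin=margin)


@dataclass
class LipidCountSeries:
    """Tidy per-(frame, species, leaflet) in-region molecule counts."""

    table: pd.DataFrame       # columns: frame, time_ns, species, leaflet, count
    region: RingRegion
    totals: pd.DataFrame      # per (frame, species, leaflet) totals

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def count_in_region(
    traj: Trajectory,
    leaflets: LeafletAssignment,
    region: RingRegion,
) -> LipidCountSeries:
    """Count lipid molecules inside the region per frame/species/leaflet."""
    lt = traj.topology.lipid_table()
    center = np.array([region.center[0], region.center[1], 0.0])
    species = lt.species
    rows = []
    totals = []
    box = traj.box
    species_names = sorted(set(species.tolist()))
    for f in range(traj.n_frames):
        pos = traj.xyz[f, lt.first_phosphate].copy()
        pos[:, 2] = 0.0
        d = lateral_dist(pos, center, box)
        inside = d <= region.effective_radius
        lab = leaflets.labels[f]
        for sp in species_names:
            for leaf in ("upper", "lower"):
                m = (species == sp) & (lab == leaf)
                rows.append({"frame": f, "time_ns": float(traj.time[f]),
                             "species": sp, "leaflet": leaf,
                             "count": int(np.sum(m & inside))})
                totals.append({"frame": f, "species": sp, "leaflet": leaf,
                               "total": int(np.sum(m))})
    return LipidCountSeries(table=pd.DataFrame(rows), region=region,
                            totals=pd.DataFrame(totals))


def enrichment_ratio(
    series: LipidCountSeries,
    box: np.ndarray,
) -> pd.DataFrame:
    """Per-frame, per-species, per-leaflet enrichment ratio (see module doc)."""
    box_area = float(box[0] * box[1])
    area = series.region.area
    if area >= box_area:
        raise GeometryError(
            f"region area {area:.1f} nm^2 must be smaller than the box "
            f"lateral area {box_area:.1f} nm^2")
    df = series.table.merge(series.totals, on=["frame", "species", "leaflet"])
    sp_totals = df.groupby("species")["total"].sum()
    if (sp_totals == 0).any():
        bad = sp_totals.index[sp_totals == 0][0]
        raise UndefinedRatioError(
            f"species {bad} has zero total count; enrichment ratio undefined")
    # a leaflet with no molecules of the species yields an undefined (NaN) row
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(
            df["total"] > 0,
            (df["count"] / area) / (df["total"] / box_area),
            np.nan,
        )
    return df


def time_averaged_ratio(
    series: LipidCountSeries,
    box: np.ndarray,
    species: str,
    frame_lo: int,
    frame_hi: int | None = None,
) -> float:
    """Leaflet-pooled, time-averaged enrichment ratio over a frame range.

    Pools both leaflets by summing counts and totals per frame, then averages
    the per-frame pooled ratio over frames in [frame_lo, frame_hi).
    """
    frac = series.region.area / float(box[0] * box[1])
    df = series.table.merge(series.totals, on=["frame", "species", "leaflet"])
    df = df[df["species"] == species]
    if df.empty:
        raise UndefinedRatioError(
            f"species {species} is absent from the count series")
    if frame_hi is None:
        frame_hi = int(df["frame"].max()) + 1
    df = df[(df["frame"] >= frame_lo) & (df["frame"] < frame_hi)]
    if df.empty:
        raise UndefinedRatioError(f"no frames in [{frame_lo}, {frame_hi})")
    pooled = df.groupby("frame")[["count", "total"]].sum()
    if (pooled["total"] == 0).any():
        raise UndefinedRatioError(f"species {species} has zero total count")
    per_frame = (pooled["count"] / pooled["total"]) / frac
    return float(per_frame.mean())
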