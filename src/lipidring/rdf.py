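"""Protein-lipid radial distribution function with local-density normalization.

The pair-correlation function between reference beads A (one per protein
residue: backbone bead for glycine, sidechain bead otherwise) and lipid
phosphate beads B is

    g_AB(r) = <rho_B(r)> / <rho_B>_local
            = (1 / <rho_B>_local) * (1 / N_A) * sum_i sum_j delta(r_ij - r) / (4 pi r^2)

where ``<rho_B>_local`` is the density of B averaged over all spheres of
radius ``r_max`` (default 1.5 nm) around the A beads.  The continuum formula
is estimated with distance bins: per bin k,

    g_k = C_k / (n_frames * N_A * V_shell(k) * <rho_B>_local)

with ``C_k`` the raw pair count in bin k summed over frames and
``<rho_B>_local`` the mean over frames and A beads of (B count within r_max)
/ ((4/3) pi r_max^3).  The exact shell volume (4 pi / 3)(r_{k+1}^3 - r_k^3)
is used by default; a ``midpoint_4pir2`` flag reproduces the literal
4 pi r_mid^2 dr reading of the continuum formula.

Because the reference density is local (a sphere that spans the membrane
slab), g does not tend to 1 at large r the way a bulk-normalized RDF would;
values are comparable across residues and species, which is what the
analysis uses them for.

Binning convention: a pair at distance d falls in bin floor(d / bin_width)
when d <= r_max and floor(d / bin_width) < n_bins; distances are always
lateral minimum-image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BeadSelection,
    EmptySelectionError,
    GeometryError,
    NoPeakError,
    Trajectory,
)
from .geometry import neighbor_pairs
from .leaflets import LeafletAssignment


@dataclass
class RDFParams:
    r_max: float = 1.5               # nm
    bin_width: float = 0.02          # nm
    leaflet: str = "both"            # upper / lower / both
    shell_normalization: str = "exact_shell"   # or "midpoint_4pir2"
    local_density_mode: str = "joint"          # or "per_frame"
    cl_single_bead: bool = False     # count one phosphate bead per CL molecule

    def __post_init__(self) -> None:
        if not 0 < self.bin_width < self.r_max:
            raise ValueError("require 0 < bin_width < r_max")
        if self.leaflet not in ("upper", "lower", "both"):
            raise ValueError(f"unknown leaflet filter {self.leaflet!r}")
        if self.shell_normalization not in ("exact_shell", "midpoint_4pir2"):
            raise ValueError(
                f"unknown shell_normalization {self.shell_normalization!r}")
        if self.local_density_mode not in ("joint", "per_frame"):
            raise ValueError(
                f"unknown local_density_mode {self.local_density_mode!r}")


@dataclass
class RDFResult:
    bin_edges: np.ndarray      # (n_bins + 1,) nm
    g: np.ndarray              # (n_bins,) dimensionless
    pair_counts: np.ndarray    # (n_bins,) raw counts summed over frames
    n_A: int
    local_density: float       # <rho_B>_local, nm^-3
    n_frames: int
    params: RDFParams

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_mid": self.r_mid,
            "g": self.g,
            "pair_count": self.pair_counts.astype(int),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def shell_volumes(edges: np.ndarray, mode: str) -> np.ndarray:
    if mode == "exact_shell":
        return 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return 4.0 * np.pi * mids**2 * np.diff(edges)


def _b_bead_plan(
    traj: Trajectory,
    B: BeadSelection,
    leaflets: LeafletAssignment | None,
    params: RDFParams,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resolve CL-multiplicity and leaflet lookup for the B selection.

    Returns (bead ids after the cl_single_bead filter, per-bead column index
    into the leaflet assignment or None when no leaflet filter applies).
    """
    topo = traj.topology
    ids = B.bead_ids
    if params.cl_single_bead:
        lt = topo.lipid_table()
        keep_first = np.isin(ids, lt.first_phosphate)
        not_cl = topo.species[ids] != "CL"
        ids = ids[keep_first | not_cl]
    if params.leaflet == "both":
        return ids, None
    if leaflets is None:
        raise ValueError("leaflet-filtered RDF requires a LeafletAssignment")
    mols = topo.molecule_id[ids]
    cols = np.searchsorted(leaflets.molecule_ids, mols)
    bad = (cols >= len(leaflets.molecule_ids)) | \
        (leaflets.molecule_ids[np.minimum(cols, len(leaflets.molecule_ids) - 1)]
         != mols)
    if np.any(bad):
        raise EmptySelectionError(
            "leaflet-filtered RDF requires all B beads to belong to lipids")
    return ids, cols


def compute_rdf(
    traj: Trajectory,
    A: BeadSelection,
    B: BeadSelection,
    leaflets: LeafletAssignment | None = None,
    params: RDFParams | None = None,
) -> RDFResult:
    """Binned estimator of g_AB(r) (see module docstring)."""
    params = params or RDFParams()
    if len(A) == 0 or len(B) == 0:
        raise EmptySelectionError("RDF requires non-empty A and B selections")
    if np.intersect1d(A.bead_ids, B.bead_ids).size:
        raise EmptySelectionError("A and B selections must be disjoint")
    box = traj.box
    if params.r_max > min(box[0], box[1]) / 2:
        raise GeometryError(
            f"r_max={params.r_max} nm exceeds half the smallest lateral box "
            f"length ({min(box[0], box[1]) / 2:g} nm)")
    n_bins = int(np.ceil(params.r_max / params.bin_width - 1e-9))
    edges = np.arange(n_bins + 1, dtype=float) * params.bin_width
    counts = np.zeros(n_bins)
    vols = shell_volumes(edges, params.shell_normalization)
    sphere_vol = 4.0 * np.pi / 3.0 * params.r_max**3
    n_A = len(A)
    in_sphere_total = 0.0
    g_accum = np.zeros(n_bins)
    frames_with_density = 0

    base_ids, leaf_cols = _b_bead_plan(traj, B, leaflets, params)
    for f in range(traj.n_frames):
        if leaf_cols is None:
            b_ids = base_ids
        else:
            b_ids = base_ids[leaflets.labels[f, leaf_cols] == params.leaflet]
        frame_counts = np.zeros(n_bins)
        n_in_sphere = 0
        if len(b_ids):
            a_xyz = traj.xyz[f, A.bead_ids]
            b_xyz = traj.xyz[f, b_ids]
            i_idx, _j, dist = neighbor_pairs(a_xyz, b_xyz, box, params.r_max)
            n_in_sphere = len(dist)
            if len(dist):
                k = np.floor(dist / params.bin_width).astype(np.int64)
                ok = k < n_bins
                frame_counts = np.bincount(k[ok], minlength=n_bins).astype(float)
        counts += frame_counts
        in_sphere_total += n_in_sphere
        if params.local_density_mode == "per_frame":
            rho_f = n_in_sphere / (n_A * sphere_vol)
            if rho_f > 0:
                g_accum += frame_counts / (n_A * vols * rho_f)
                frames_with_density += 1

    rho_local = in_sphere_total / (traj.n_frames * n_A * sphere_vol)
    if params.local_density_mode == "per_frame":
        g = g_accum / max(frames_with_density, 1)
    elif rho_local > 0:
        g = counts / (traj.n_frames * n_A * vols * rho_local)
    else:
        g = np.zeros(n_bins)
    return RDFResult(
        bin_edges=edges, g=g, pair_counts=counts, n_A=n_A,
        local_density=rho_local, n_frames=traj.n_frames, params=params,
    )


def peak_location(result: RDFResult, r_min_search: float = 0.1) -> float:
    """Midpoint of the bin maximizing g over r_mid >= r_min_search.

    Ties resolve to the smallest r.  Raises :class:`NoPeakError` when g is
    zero everywhere in the search range.
    """
    mids = result.r_mid
    mask = mids >= r_min_search
    if not np.any(mask):
        raise NoPeakError(
            f"no bins at r >= {r_min_search} nm (r_max={result.bin_edges[-1]})")
    g = np.where(mask, result.g, -np.inf)
    if np.nanmax(g) <= 0:
        raise NoPeakError("RDF is zero everywhere in the search range")
    return float(mids[int(np.argmax(g))])
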