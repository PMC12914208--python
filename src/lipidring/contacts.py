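"""Residue-cardiolipin contact detection and interaction-frequency statistics.

A residue instance (one residue of one subunit) is *in contact* in a sampled
frame when any cardiolipin headgroup (phosphate) bead lies within the cutoff
(default 0.6 nm) of the residue's reference bead — backbone bead for glycine,
sidechain bead otherwise.  Frames are sampled at a fixed interval (default
1 ns).  The interaction frequency of a residue is the fraction of sampled
frames in which it maintained contact.

Contacts are leaflet-resolved: a contact is attributed to the leaflet of the
contacting cardiolipin at that frame; a frame with contacts from both
leaflets counts once toward the total (union) and once in each leaflet's
tally, so every frequency stays in [0, 1] and each per-leaflet frequency is
bounded by the total.

Default residue sets are the membrane-facing key residues: basic PHB1
K4/R41/K63 and PHB2 K6/R17/R54/R71; polar PHB1 H55 and PHB2 Y34/G35/S39/Y77.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnnotationError,
    EmptySelectionError,
    StrideError,
    Trajectory,
)
from .geometry import min_image_dist
from .leaflets import LeafletAssignment
from .select import expand_residue_set, residue_reference_beads, select_beads

DEFAULT_RESIDUE_SETS = {
    "PHB1": [4, 41, 55, 63],
    "PHB2": [6, 17, 34, 35, 39, 54, 71, 77],
}

RESIDUE_CLASSES = {
    "PHB1": {4: "basic", 41: "basic", 55: "polar", 63: "basic"},
    "PHB2": {6: "basic", 17: "basic", 34: "polar", 35: "polar", 39: "polar",
             54: "basic", 71: "basic", 77: "polar"},
}


@dataclass
class ContactParams:
    cutoff: float = 0.6                      # nm
    sample_stride: float = 1.0               # ns
    residue_sets: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_RESIDUE_SETS.items()})
    leaflet_resolved: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not any(self.residue_sets.values()):
            raise ValueError("residue sets must be non-empty")


@dataclass
class ContactSeries:
    """Boolean matrices [residue instance x sampled frame]."""

    instances: list[tuple[int, int, str, int]]  # (mol, seq, species, subunit)
    sampled_frames: np.ndarray                  # trajectory frame indices
    total: np.ndarray                           # (n_inst, n_samples) bool
    upper: np.ndarray | None = None
    lower: np.ndarray | None = None

    @property
    def n_instances(self) -> int:
        return self.total.shape[0]

    @property
    def n_samples(self) -> int:
        return self.total.shape[1]


@dataclass
class InteractionFrequency:
    """Per-residue-instance fraction of sampled frames in contact."""

    instances: list[tuple[int, int, str, int]]
    total: np.ndarray
    upper: np.ndarray | None = None
    lower: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (mol, seq, sp, sub) in enumerate(self.instances):
            row = {"subunit": sub, "species": sp, "molecule_id": mol,
                   "residue_seq": seq, "frequency": self.total[i]}
            if self.upper is not None:
                row["frequency_upper"] = self.upper[i]
            if self.lower is not None:
                row["frequency_lower"] = self.lower[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def _sampled_frames(traj: Trajectory, sample_stride: float) -> np.ndarray:
    stride = traj.stride
    if stride <= 0:
        return np.arange(traj.n_frames)
    k = sample_stride / stride
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise StrideError(
            f"sample stride {sample_stride} ns is not a positive multiple of "
            f"the trajectory stride {stride} ns")
    return np.arange(0, traj.n_frames, int(round(k)))


def compute_contacts(
    traj: Trajectory,
    leaflets: LeafletAssignment | None,
    params: ContactParams | None = None,
) -> ContactSeries:
    """Detect residue-cardiolipin contacts on the sampled frames."""
    params = params or ContactParams()
    topo = traj.topology
    instances = expand_residue_set(topo, params.residue_sets)
    ref = residue_reference_beads(topo, [(m, s) for m, s, _sp, _k in instances])
    cl = select_beads(topo, species="CL", role="phosphate")
    if len(cl) == 0:
        raise EmptySelectionError("no cardiolipin phosphate beads in topology")
    frames = _sampled_frames(traj, params.sample_stride)
    resolved = params.leaflet_resolved and leaflets is not None
    if params.leaflet_resolved and leaflets is None:
        raise ValueError("leaflet-resolved contacts require a LeafletAssignment")
    cols = (np.searchsorted(leaflets.molecule_ids, topo.molecule_id[cl.bead_ids])
            if resolved else None)

    n_inst = len(instances)
    total = np.zeros((n_inst, len(frames)), dtype=bool)
    upper = np.zeros_like(total) if resolved else None
    lower = np.zeros_like(total) if resolved else None
    box = traj.box
    for s, f in enumerate(frames):
        a = traj.xyz[f, ref.bead_ids]           # (n_inst, 3)
        b = traj.xyz[f, cl.bead_ids]            # (n_cl_beads, 3)
        d = min_image_dist(a[:, None, :], b[None, :, :], box)
        within = d <= params.cutoff
        total[:, s] = within.any(axis=1)
        if resolved:
            lab = leaflets.labels[f, cols]
            upper[:, s] = (within & (lab == "upper")[None, :]).any(axis=1)
            lower[:, s] = (within & (lab == "lower")[None, :]).any(axis=1)
    return ContactSeries(instances=instances, sampled_frames=frames,
                         total=total, upper=upper, lower=lower)


def interaction_frequency(series: ContactSeries) -> InteractionFrequency:
    """Fraction of sampled frames in contact, per residue instance."""
    if series.n_samples == 0:
        raise ValueError("contact series has no sampled frames")
    return InteractionFrequency(
        instances=series.instances,
        total=series.total.mean(axis=1),
        upper=None if series.upper is None else series.upper.mean(axis=1),
        lower=None if series.lower is None else series.lower.mean(axis=1),
    )


def residue_distance_profile(
    traj: Trajectory,
    leaflets: LeafletAssignment,
    residue_sets: dict[str, list[int]] | None = None,
    residue_classes: dict[str, dict[int, str]] | None = None,
    leaflet: str = "upper",
    species: tuple[str, ...] = ("CL",),
    r_max: float = 1.5,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Histogram of residue classes vs distance from the lipid headgroup plane.

    For each residue instance and frame the distance is the minimum
    minimum-image distance from the residue's reference bead to any phosphate
    bead of the chosen species and leaflet.  Returns a tidy frame-averaged
    histogram (columns: class, r_lo, r_hi, mean_count).
    """
    residue_sets = residue_sets or DEFAULT_RESIDUE_SETS
    residue_classes = residue_classes or RESIDUE_CLASSES
    topo = traj.topology
    instances = expand_residue_set(topo, residue_sets)
    classes = []
    for mol, seq, sp, _k in instances:
        try:
            classes.append(residue_classes[sp][seq])
        except KeyError:
            raise AnnotationError(
                f"residue {sp} {seq} has no class annotation") from None
    ref = residue_reference_beads(topo, [(m, s) for m, s, _sp, _k in instances])
    phos = select_beads(topo, species=list(species), role="phosphate")
    cols = np.searchsorted(leaflets.molecule_ids,
                           topo.molecule_id[phos.bead_ids])
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    class_names = sorted(set(classes))
    acc = {c: np.zeros(n_bins) for c in class_names}
    box = traj.box
    for f in range(traj.n_frames):
        active = phos.bead_ids[leaflets.labels[f, cols] == leaflet]
        if len(active) == 0:
            raise EmptySelectionError(
                f"no phosphate beads on leaflet {leaflet!r} at frame {f}")
        a = traj.xyz[f, ref.bead_ids]
        b = traj.xyz[f, active]
        d = min_image_dist(a[:, None, :], b[None, :, :], box).min(axis=1)
        for c in class_names:
            sel = d[[cls == c for cls in classes]]
            h, _ = np.histogram(sel, bins=edges)
            acc[c] += h
    rows = []
    for c in class_names:
        for k in range(n_bins):
            rows.append({"class": c, "r_lo": edges[k], "r_hi": edges[k + 1],
                         "mean_count": acc[c][k] / traj.n_frames})
    return pd.DataFrame(rows)
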