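"""Core domain containers for coarse-grained membrane + protein-ring systems.

The object model is deliberately small: a :class:`BeadTopology` describes every
coarse-grained bead once (species, molecule, residue annotation, bead role,
leaflet hint), a :class:`Trajectory` holds an ``(n_frames, n_beads, 3)`` nm
coordinate array over an orthorhombic box with a uniform output stride in ns,
and a :class:`BeadSelection` is an ordered subset of bead ids with a
human-readable provenance string.

Conventions used throughout the package:

* lengths in nm, times in ns;
* the membrane plane is xy, the membrane normal is z;
* x and y are periodic (minimum-image), z is not;
* lipid molecules are identified by their phosphate/headgroup bead(s) —
  cardiolipin carries two phosphate beads, POPC/POPE carry one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

SPECIES = ("POPC", "POPE", "CL", "PHB1", "PHB2")
LIPID_SPECIES = ("POPC", "POPE", "CL")
PROTEIN_SPECIES = ("PHB1", "PHB2")
BEAD_ROLES = ("phosphate", "backbone", "sidechain", "tail", "other")
LEAFLET_LABELS = ("upper", "lower", "none")

#: number of phosphate beads each lipid species carries
PHOSPHATES_PER_LIPID = {"POPC": 1, "POPE": 1, "CL": 2}


class LipidRingError(Exception):
    """Base class for all package errors."""


class FormatError(LipidRingError):
    """A file could not be parsed under the declared format."""


class AnnotationError(LipidRingError):
    """A residue/atom name could not be mapped to a species/role."""


class TopologyError(LipidRingError):
    """Topology invariants violated, or trajectory/topology mismatch."""


class StrideError(LipidRingError):
    """Frame times are not uniformly spaced."""


class EmptySelectionError(LipidRingError):
    """A bead selection matched nothing; downstream stages refuse to run."""


class ResidueLookupError(LipidRingError):
    """A requested (subunit, residue) does not exist in the topology."""


class GeometryError(LipidRingError):
    """A geometric precondition failed (box too small, no far-field...)."""


class PackingError(LipidRingError):
    """Requested lipid count does not fit the box at a physical area/lipid."""


class WindowError(LipidRingError):
    """An empty or out-of-range frame window."""


class CoverageError(LipidRingError):
    """Two gridded fields share no occupied cells."""


class RingFitError(LipidRingError):
    """Circle fit to protein bead positions is degenerate."""


class NoPeakError(LipidRingError):
    """An RDF has no nonzero bin in the search range."""


class UndefinedRatioError(LipidRingError):
    """Enrichment ratio requested for a species with zero total count."""


class ConfigError(LipidRingError):
    """Invalid pipeline configuration."""


class UnknownPresetError(LipidRingError):
    """Unknown generator preset name."""


@dataclass(frozen=True)
class Bead:
    """One coarse-grained interaction site.

    ``residue_seq`` is the 1-based residue number for protein beads and 0 for
    lipid beads.  ``leaflet_hint`` records the leaflet a lipid was built in
    (generator ground truth); protein beads always carry ``"none"``.
    """

    bead_id: int
    molecule_id: int
    species: str
    residue_name: str
    residue_seq: int
    bead_role: str
    leaflet_hint: str


class BeadTopology:
    """Ordered, validated collection of beads.

    Internally stored as parallel numpy arrays so selections and per-frame
    analyses vectorise; :meth:`beads` iterates `Bead` views for convenience.
    """

    def __init__(self, beads: Sequence[Bead]):
        if len(beads) == 0:
            raise TopologyError("topology must contain at least one bead")
        self.bead_id = np.asarray([b.bead_id for b in beads], dtype=np.int64)
        self.molecule_id = np.asarray([b.molecule_id for b in beads], dtype=np.int64)
        self.species = np.asarray([b.species for b in beads], dtype="U4")
        self.residue_name = np.asarray([b.residue_name for b in beads], dtype="U5")
        self.residue_seq = np.asarray([b.residue_seq for b in beads], dtype=np.int64)
        self.bead_role = np.asarray([b.bead_role for b in beads], dtype="U9")
        self.leaflet_hint = np.asarray([b.leaflet_hint for b in beads], dtype="U5")
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        molecule_id: np.ndarray,
        species: np.ndarray,
        residue_name: np.ndarray,
        residue_seq: np.ndarray,
        bead_role: np.ndarray,
        leaflet_hint: np.ndarray,
    ) -> "BeadTopology":
        obj = cls.__new__(cls)
        n = len(molecule_id)
        obj.bead_id = np.arange(n, dtype=np.int64)
        obj.molecule_id = np.asarray(molecule_id, dtype=np.int64)
        obj.species = np.asarray(species, dtype="U4")
        obj.residue_name = np.asarray(residue_name, dtype="U5")
        obj.residue_seq = np.asarray(residue_seq, dtype=np.int64)
        obj.bead_role = np.asarray(bead_role, dtype="U9")
        obj.leaflet_hint = np.asarray(leaflet_hint, dtype="U5")
        obj.validate()
        return obj

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        n = self.n_beads
        if not np.array_equal(self.bead_id, np.arange(n)):
            raise TopologyError("bead ids must be unique and contiguous from 0")
        bad = set(np.unique(self.species)) - set(SPECIES)
        if bad:
            raise TopologyError(f"unknown species: {sorted(bad)}")
        bad = set(np.unique(self.bead_role)) - set(BEAD_ROLES)
        if bad:
            raise TopologyError(f"unknown bead roles: {sorted(bad)}")
        bad = set(np.unique(self.leaflet_hint)) - set(LEAFLET_LABELS)
        if bad:
            raise TopologyError(f"unknown leaflet hints: {sorted(bad)}")
        is_protein = np.isin(self.species, PROTEIN_SPECIES)
        if np.any(self.leaflet_hint[is_protein] != "none"):
            raise TopologyError("protein beads must have leaflet_hint='none'")
        # per-lipid phosphate multiplicity: CL exactly 2, POPC/POPE exactly 1
        for sp in LIPID_SPECIES:
            mask = (self.species == sp) & (self.bead_role == "phosphate")
            mols, counts = np.unique(self.molecule_id[mask], return_counts=True)
            want = PHOSPHATES_PER_LIPID[sp]
            if np.any(counts != want):
                off = mols[counts != want][0]
                raise TopologyError(
                    f"{sp} molecule {off} has {counts[counts != want][0]} phosphate "
                    f"beads, expected {want}"
                )
            # also catch molecules of this species with zero phosphates
            all_mols = np.unique(self.molecule_id[self.species == sp])
            if len(all_mols) != len(mols):
                missing = sorted(set(all_mols) - set(mols))[0]
                raise TopologyError(f"{sp} molecule {missing} has no phosphate bead")
        # every protein residue needs a backbone bead; non-glycine a sidechain
        if np.any(is_protein):
            key = np.stack(
                [self.molecule_id[is_protein], self.residue_seq[is_protein]], axis=1
            )
            for mol, seq in np.unique(key, axis=0):
                m = is_protein & (self.molecule_id == mol) & (self.residue_seq == seq)
                roles = set(self.bead_role[m])
                rname = self.residue_name[m][0]
                if "backbone" not in roles:
                    raise TopologyError(
                        f"protein residue ({mol}, {seq}) lacks a backbone bead"
                    )
                if rname not in ("GLY", "G") and "sidechain" not in roles:
                    raise TopologyError(
                        f"non-glycine residue ({mol}, {seq}, {rname}) lacks a "
                        "sidechain bead"
                    )

    # -- accessors ------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.bead_id)

    def beads(self) -> Iterator[Bead]:
        for i in range(self.n_beads):
            yield Bead(
                int(self.bead_id[i]),
                int(self.molecule_id[i]),
                str(self.species[i]),
                str(self.residue_name[i]),
                int(self.residue_seq[i]),
                str(self.bead_role[i]),
                str(self.leaflet_hint[i]),
            )

    @property
    def is_lipid(self) -> np.ndarray:
        return np.isin(self.species, LIPID_SPECIES)

    @property
    def is_protein(self) -> np.ndarray:
        return np.isin(self.species, PROTEIN_SPECIES)

    def lipid_table(self) -> "LipidTable":
        return LipidTable(self)

    def protein_subunits(self) -> list[tuple[int, str]]:
        """Ordered ``(molecule_id, species)`` of protein subunits."""
        out: list[tuple[int, str]] = []
        seen: set[int] = set()
        for mol, sp in zip(self.molecule_id[self.is_protein],
                           self.species[self.is_protein]):
            if mol not in seen:
                seen.add(int(mol))
                out.append((int(mol), str(sp)))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BeadTopology):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("bead_id", "molecule_id", "species", "residue_name",
                      "residue_seq", "bead_role", "leaflet_hint")
        )

    def __repr__(self) -> str:
        n_lip = int(np.sum(self.is_lipid))
        n_pro = int(np.sum(self.is_protein))
        return f"<BeadTopology {self.n_beads} beads ({n_lip} lipid, {n_pro} protein)>"


class LipidTable:
    """Per-lipid-molecule view of a topology.

    ``first_phosphate`` indexes the bead that represents the molecule in
    per-molecule analyses (lipid counting, leaflet assignment); for CL the
    second phosphate bead inherits whatever label the first receives.
    """

    def __init__(self, topology: BeadTopology):
        mask = topology.is_lipid & (topology.bead_role == "phosphate")
        if not np.any(mask):
            raise EmptySelectionError("topology contains no lipid phosphate beads")
        idx = np.flatnonzero(mask)
        mols = topology.molecule_id[idx]
        # stable per-molecule grouping in topology order
        order = np.argsort(mols, kind="stable")
        first = order[np.concatenate(([True], np.diff(mols[order]) > 0))]
        self.molecule_id = mols[first]
        self.first_phosphate = idx[first]
        self.species = topology.species[self.first_phosphate]
        self.leaflet_hint = topology.leaflet_hint[self.first_phosphate]
        self.all_phosphates = idx  # every phosphate bead, topology order
        self.phosphate_molecule = mols
        # map molecule_id -> row for bead-level lookups
        self._row = {int(m): i for i, m in enumerate(self.molecule_id)}

    @property
    def n_lipids(self) -> int:
        return len(self.molecule_id)

    def row_of(self, molecule_id: int) -> int:
        return self._row[int(molecule_id)]

    def rows_for_beads(self, bead_phos_mols: np.ndarray) -> np.ndarray:
        return np.asarray([self._row[int(m)] for m in bead_phos_mols], dtype=np.int64)


@dataclass
class Frame:
    """A single trajectory frame: time (ns), box (nm, orthorhombic), coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def validate(self) -> None:
        box = np.asarray(self.box, dtype=float)
        if box.shape != (3,) or np.any(box <= 0):
            raise GeometryError(f"box must be 3 positive lengths, got {box}")
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("non-finite coordinates in frame")
        xy = self.coords[:, :2]
        if np.any(xy < 0) or np.any(xy >= box[:2]):
            raise GeometryError("x,y coordinates must be wrapped into [0, L)")


class Trajectory:
    """Frames of bead coordinates over a fixed topology and box.

    ``xyz`` has shape ``(n_frames, n_beads, 3)`` in nm; ``time`` is in ns with
    a strictly uniform stride; ``box`` is a constant orthorhombic box.
    """

    def __init__(self, topology: BeadTopology, xyz: np.ndarray,
                 time: np.ndarray, box: np.ndarray):
        xyz = np.asarray(xyz, dtype=float)
        time = np.asarray(time, dtype=float)
        box = np.asarray(box, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise TopologyError(f"xyz must be (n_frames, n_beads, 3), got {xyz.shape}")
        if xyz.shape[1] != topology.n_beads:
            raise TopologyError(
                f"trajectory has {xyz.shape[1]} beads but topology has "
                f"{topology.n_beads}"
            )
        if xyz.shape[0] != len(time):
            raise TopologyError("time array length must match frame count")
        if len(time) < 1:
            raise TopologyError("trajectory must contain at least one frame")
        if box.shape != (3,) or np.any(box <= 0):
            raise GeometryError(f"box must be 3 positive lengths, got {box}")
        if len(time) >= 2:
            dt = np.diff(time)
            if np.any(dt <= 0):
                k = int(np.argmax(dt <= 0))
                raise StrideError(f"frame times not strictly increasing at frame {k + 1}")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                k = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9)))
                raise StrideError(
                    f"non-uniform time step at frame {k + 1}: "
                    f"{dt[k]:g} ns vs {dt[0]:g} ns"
                )
        self.topology = topology
        self.xyz = xyz
        self.time = time
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_beads(self) -> int:
        return self.xyz.shape[1]

    @property
    def stride(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.time[1] - self.time[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.time[i]), box=self.box, coords=self.xyz[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __repr__(self) -> str:
        return (f"<Trajectory {self.n_frames} frames x {self.n_beads} beads, "
                f"stride {self.stride:g} ns>")


@dataclass
class BeadSelection:
    """Ordered subset of topology bead ids with provenance."""

    bead_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.bead_ids = np.asarray(self.bead_ids, dtype=np.int64)
        if len(np.unique(self.bead_ids)) != len(self.bead_ids):
            raise TopologyError("selection contains duplicate bead ids")

    def validate_against(self, topology: BeadTopology) -> None:
        if len(self.bead_ids) and (
            self.bead_ids.min() < 0 or self.bead_ids.max() >= topology.n_beads
        ):
            raise TopologyError("selection references bead ids outside topology")

    def __len__(self) -> int:
        return len(self.bead_ids)
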