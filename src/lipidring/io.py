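"""Readers and writers for topologies and trajectories.

Formats:

* **internal JSON** (topology) — versioned, self-describing, lossless; the
  native interchange format of this package.
* **GRO / PDB** (topology + one coordinate frame) — read through mdtraj;
  species and bead roles are derived from residue/atom names via a mapping
  table (Martini-style defaults: ``PO4``/``PO41``/``PO42`` are phosphates,
  ``BB`` backbone, ``SC1..SC4`` sidechains).  GRO carries no chain record, so
  protein subunit boundaries are inferred from residue-number resets and
  subunit species alternate PHB1/PHB2 starting with PHB1 — the same
  convention the generator writes.
* **XTC / DCD** (trajectories) — via mdtraj's format backends; DCD stores
  Angstrom and is converted to nm on read/write.
* **internal NPZ** (trajectory) — versioned numpy container with exact
  float64 coordinates, used as the plain fallback format.

All coordinates are nm and times ns once in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from mdtraj.formats import DCDTrajectoryFile, XTCTrajectoryFile

from .core import (
    AnnotationError,
    BeadTopology,
    FormatError,
    Frame,
    StrideError,
    TopologyError,
    Trajectory,
)

TOPOLOGY_FORMAT_NAME = "lipidring-topology"
TRAJECTORY_FORMAT_NAME = "lipidring-trajectory"
FORMAT_VERSION = 1

#: default (residue name -> atom name -> (species, role)) mapping.
#: ``*`` matches any atom name not listed explicitly.
DEFAULT_BEAD_MAP: dict[str, dict[str, tuple[str, str]]] = {
    "POPC": {"PO4": ("POPC", "phosphate"), "NC3": ("POPC", "other"),
             "*": ("POPC", "tail")},
    "POPE": {"PO4": ("POPE", "phosphate"), "NH3": ("POPE", "other"),
             "*": ("POPE", "tail")},
    "CDL2": {"PO41": ("CL", "phosphate"), "PO42": ("CL", "phosphate"),
             "PO4": ("CL", "phosphate"), "*": ("CL", "tail")},
    "CDL1": {"PO41": ("CL", "phosphate"), "PO42": ("CL", "phosphate"),
             "*": ("CL", "tail")},
    "CL": {"PO41": ("CL", "phosphate"), "PO42": ("CL", "phosphate"),
           "*": ("CL", "tail")},
}

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

PROTEIN_ATOM_ROLES = {"BB": "backbone", "CA": "backbone"}


def _protein_role(atom_name: str) -> str:
    if atom_name in PROTEIN_ATOM_ROLES:
        return PROTEIN_ATOM_ROLES[atom_name]
    if atom_name.startswith("SC"):
        return "sidechain"
    raise AnnotationError(f"cannot assign a role to protein atom "
                          f"{atom_name!r}")


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

def write_topology_json(topology: BeadTopology, frame: Frame,
                        path: str | Path) -> None:
    doc = {
        "format": TOPOLOGY_FORMAT_NAME,
        "version": FORMAT_VERSION,
        "box_nm": [float(b) for b in frame.box],
        "time_ns": float(frame.time),
        "beads": [
            {
                "molecule_id": int(topology.molecule_id[i]),
                "species": str(topology.species[i]),
                "residue_name": str(topology.residue_name[i]),
                "residue_seq": int(topology.residue_seq[i]),
                "bead_role": str(topology.bead_role[i]),
                "leaflet_hint": str(topology.leaflet_hint[i]),
                "xyz_nm": [float(x) for x in frame.coords[i]],
            }
            for i in range(topology.n_beads)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def _read_topology_json(path: Path) -> tuple[BeadTopology, Frame]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON (line {e.lineno})") from e
    if doc.get("format") != TOPOLOGY_FORMAT_NAME:
        raise FormatError(f"{path}: not a {TOPOLOGY_FORMAT_NAME} file")
    if doc.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported version {doc.get('version')}")
    beads = doc["beads"]
    topo = BeadTopology.from_arrays(
        np.asarray([b["molecule_id"] for b in beads]),
        np.asarray([b["species"] for b in beads]),
        np.asarray([b["residue_name"] for b in beads]),
        np.asarray([b["residue_seq"] for b in beads]),
        np.asarray([b["bead_role"] for b in beads]),
        np.asarray([b["leaflet_hint"] for b in beads]),
    )
    coords = np.asarray([b["xyz_nm"] for b in beads], dtype=float)
    frame = Frame(time=float(doc.get("time_ns", 0.0)),
                  box=np.asarray(doc["box_nm"], dtype=float), coords=coords)
    frame.validate()
    return topo, frame


def _annotate_mdtraj_topology(
    md_top, bead_map: dict[str, dict[str, tuple[str, str]]],
    has_chains: bool,
) -> BeadTopology:
    mol_id, species, resname, resseq, role, hint = [], [], [], [], [], []
    next_mol = -1
    prev_res_index = None
    prev_protein_seq = None
    prev_chain = None
    protein_subunit_count = 0
    current_is_protein = False
    for atom in md_top.atoms:
        res = atom.residue
        rname = res.name
        aname = atom.name
        is_protein = rname in PROTEIN_RESNAMES
        new_res = res.index != prev_res_index
        if is_protein:
            new_subunit = (
                not current_is_protein
                or (has_chains and res.chain.index != prev_chain)
                or (not has_chains and new_res and prev_protein_seq is not None
                    and res.resSeq <= prev_protein_seq)
            )
            if new_subunit:
                next_mol += 1
                protein_subunit_count += 1
            sp = "PHB1" if (protein_subunit_count - 1) % 2 == 0 else "PHB2"
            mol_id.append(next_mol)
            species.append(sp)
            resname.append(rname)
            resseq.append(int(res.resSeq))
            role.append(_protein_role(aname))
            hint.append("none")
            if new_res:
                prev_protein_seq = int(res.resSeq)
            current_is_protein = True
        else:
            if rname not in bead_map:
                raise AnnotationError(
                    f"residue name {rname!r} has no species/role mapping")
            table = bead_map[rname]
            if aname in table:
                sp, rl = table[aname]
            elif "*" in table:
                sp, rl = table["*"]
            else:
                raise AnnotationError(
                    f"atom name {aname!r} of residue {rname!r} has no "
                    "species/role mapping")
            if new_res:
                next_mol += 1
            mol_id.append(next_mol)
            species.append(sp)
            resname.append(rname)
            resseq.append(0)
            role.append(rl)
            hint.append("none")
            current_is_protein = False
        prev_res_index = res.index
        prev_chain = res.chain.index
    return BeadTopology.from_arrays(
        np.asarray(mol_id), np.asarray(species), np.asarray(resname),
        np.asarray(resseq), np.asarray(role), np.asarray(hint),
    )


def _infer_leaflet_hints(topo: BeadTopology, coords: np.ndarray) -> None:
    """Assign upper/lower hints to lipid beads by z sign about the mean."""
    lip = topo.is_lipid
    if not np.any(lip):
        return
    mid = float(np.mean(coords[lip & (topo.bead_role == "phosphate"), 2]))
    topo.leaflet_hint[lip] = np.where(coords[lip, 2] > mid, "upper", "lower")
    # beads of one molecule share the first bead's hint
    for mol in np.unique(topo.molecule_id[lip]):
        m = lip & (topo.molecule_id == mol)
        topo.leaflet_hint[m] = topo.leaflet_hint[np.flatnonzero(m)[0]]


def read_topology(
    path: str | Path,
    format: str | None = None,
    bead_map: dict[str, dict[str, tuple[str, str]]] | None = None,
) -> tuple[BeadTopology, Frame]:
    """Read a topology + embedded coordinate frame.

    ``format`` is one of ``{"GRO", "PDB", "JSON"}``; inferred from the file
    suffix when omitted.
    """
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "JSON":
        return _read_topology_json(path)
    if fmt not in ("GRO", "PDB"):
        raise FormatError(f"unknown topology format {fmt!r}")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file (line 1)")
    try:
        t = md.load(str(path))
    except Exception as e:  # mdtraj raises assorted types on bad input
        raise FormatError(f"{path}: could not parse as {fmt}: {e}") from e
    topo = _annotate_mdtraj_topology(t.topology, bead_map or DEFAULT_BEAD_MAP,
                                     has_chains=(fmt == "PDB"))
    coords = np.asarray(t.xyz[0], dtype=float)
    if t.unitcell_lengths is None:
        raise FormatError(f"{path}: no box information")
    box = np.asarray(t.unitcell_lengths[0], dtype=float)
    coords[:, 0] %= box[0]
    coords[:, 1] %= box[1]
    _infer_leaflet_hints(topo, coords)
    frame = Frame(time=0.0, box=box, coords=coords)
    frame.validate()
    return topo, frame


def write_topology_gro(topology: BeadTopology, frame: Frame,
                       path: str | Path) -> None:
    """Write a GRO file (fixed-format, nm).

    Lipid atom names follow the Martini convention (``PO4`` for POPC/POPE,
    ``PO41``/``PO42`` for cardiolipin); protein beads are ``BB``/``SC1``.
    GRO residue ids wrap at 100000.
    """
    lines = ["lipidring topology", f"{topology.n_beads:5d}"]
    lipid_res = 0
    prev_key: tuple[int, int] | None = None
    cl_phos_counter: dict[int, int] = {}
    for i in range(topology.n_beads):
        sp = str(topology.species[i])
        rl = str(topology.bead_role[i])
        key = (int(topology.molecule_id[i]), int(topology.residue_seq[i]))
        if key != prev_key:
            lipid_res += 1
            prev_key = key
        # protein beads keep their true residue number so subunit boundaries
        # (residue-number resets) survive the round trip; lipids get a
        # running residue counter
        is_protein = sp in ("PHB1", "PHB2")
        gro_res = int(topology.residue_seq[i]) if is_protein else lipid_res
        if sp in ("POPC", "POPE"):
            aname = {"phosphate": "PO4", "other": "NC3",
                     "tail": "C1A"}.get(rl, "X")
            rname = sp
        elif sp == "CL":
            if rl == "phosphate":
                n = cl_phos_counter.get(key[0], 0) + 1
                cl_phos_counter[key[0]] = n
                aname = f"PO4{n}"
            else:
                aname = "C1A"
            rname = "CDL2"
        else:
            aname = "BB" if rl == "backbone" else "SC1"
            rname = str(topology.residue_name[i])
        x, y, z = frame.coords[i]
        lines.append(
            f"{gro_res % 100000:5d}{rname:<5s}{aname:>5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = frame.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_topology(topology: BeadTopology, frame: Frame, path: str | Path,
                   format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "JSON":
        write_topology_json(topology, frame, path)
    elif fmt == "GRO":
        write_topology_gro(topology, frame, path)
    else:
        raise FormatError(f"unsupported topology output format {fmt!r}")


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write XTC (nm), DCD (Angstrom) or internal NPZ (exact nm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "NPZ":
        np.savez(
            path,
            format=np.array(TRAJECTORY_FORMAT_NAME),
            version=np.array(FORMAT_VERSION),
            xyz_nm=traj.xyz,
            time_ns=traj.time,
            box_nm=traj.box,
        )
    elif fmt == "XTC":
        with XTCTrajectoryFile(str(path), "w") as f:
            box = np.tile(np.diag(traj.box)[None, :, :], (traj.n_frames, 1, 1))
            f.write(xyz=traj.xyz.astype(np.float32), time=traj.time,
                    box=box.astype(np.float32))
    elif fmt == "DCD":
        with DCDTrajectoryFile(str(path), "w") as f:
            lengths = np.tile(traj.box[None, :] * 10.0, (traj.n_frames, 1))
            angles = np.full((traj.n_frames, 3), 90.0)
            f.write(xyz=(traj.xyz * 10.0).astype(np.float32),
                    cell_lengths=lengths.astype(np.float32),
                    cell_angles=angles.astype(np.float32))
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")


def read_trajectory(path: str | Path, topology: BeadTopology,
                    format: str | None = None) -> Trajectory:
    """Read XTC/DCD/NPZ into a :class:`Trajectory` (coordinates in nm).

    DCD carries no time axis; frames are assumed 1 ns apart.  Bead count must
    match the topology.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "NPZ":
        with np.load(path) as d:
            if str(d["format"]) != TRAJECTORY_FORMAT_NAME:
                raise FormatError(f"{path}: not a {TRAJECTORY_FORMAT_NAME} file")
            xyz, time, box = d["xyz_nm"], d["time_ns"], d["box_nm"]
    elif fmt == "XTC":
        with XTCTrajectoryFile(str(path)) as f:
            xyz, time, _step, boxmat = f.read()
        box = np.diag(boxmat[0]).astype(float)
        xyz = xyz.astype(float)
        time = time.astype(float)
    elif fmt == "DCD":
        with DCDTrajectoryFile(str(path)) as f:
            xyz, lengths, _angles = f.read()
        xyz = xyz.astype(float) / 10.0
        box = lengths[0].astype(float) / 10.0
        time = np.arange(len(xyz), dtype=float)
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")
    if xyz.shape[1] != topology.n_beads:
        raise TopologyError(
            f"{path}: trajectory has {xyz.shape[1]} beads but topology has "
            f"{topology.n_beads}")
    for k in (0, 1):
        xyz[:, :, k] %= box[k]
    return Trajectory(topology, xyz, time, box)
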