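"""Bead selection utilities.

Two selection idioms recur in every analysis stage: filtering beads by
species/role (e.g. all cardiolipin phosphate beads), and resolving the single
*reference bead* of a protein residue — the backbone bead for glycine, the
(first) sidechain bead for every other residue type.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BeadSelection,
    BeadTopology,
    EmptySelectionError,
    ResidueLookupError,
)

GLYCINE_NAMES = ("GLY", "G")


def select_beads(
    topology: BeadTopology,
    species: str | list[str] | None = None,
    role: str | list[str] | None = None,
    residues: list[tuple[int, int]] | None = None,
) -> BeadSelection:
    """Select beads by species, bead role and/or (molecule_id, residue_seq).

    Omitted query components apply no filter.  The result preserves topology
    order and is idempotent.  An empty result raises
    :class:`EmptySelectionError` so downstream stages never silently run on
    nothing.
    """
    mask = np.ones(topology.n_beads, dtype=bool)
    parts = []
    if species is not None:
        sp = [species] if isinstance(species, str) else list(species)
        mask &= np.isin(topology.species, sp)
        parts.append(f"species={','.join(sp)}")
    if role is not None:
        rl = [role] if isinstance(role, str) else list(role)
        mask &= np.isin(topology.bead_role, rl)
        parts.append(f"role={','.join(rl)}")
    if residues is not None:
        rmask = np.zeros(topology.n_beads, dtype=bool)
        for mol, seq in residues:
            rmask |= (topology.molecule_id == mol) & (topology.residue_seq == seq)
        mask &= rmask
        parts.append(f"residues={residues}")
    ids = np.flatnonzero(mask)
    provenance = " & ".join(parts) if parts else "all"
    if len(ids) == 0:
        raise EmptySelectionError(f"selection matched no beads: {provenance}")
    return BeadSelection(bead_ids=ids, provenance=provenance)


def residue_reference_beads(
    topology: BeadTopology, residues: list[tuple[int, int]]
) -> BeadSelection:
    """One reference bead per requested (molecule_id, residue_seq).

    Glycine residues are represented by their backbone bead; every other
    residue by its first sidechain bead.
    """
    ids = []
    for mol, seq in residues:
        m = (
            topology.is_protein
            & (topology.molecule_id == mol)
            & (topology.residue_seq == seq)
        )
        if not np.any(m):
            raise ResidueLookupError(
                f"residue (molecule {mol}, seq {seq}) not found in topology"
            )
        rname = str(topology.residue_name[np.flatnonzero(m)[0]])
        want_role = "backbone" if rname in GLYCINE_NAMES else "sidechain"
        cand = np.flatnonzero(m & (topology.bead_role == want_role))
        if len(cand) == 0:
            raise ResidueLookupError(
                f"residue (molecule {mol}, seq {seq}, {rname}) has no "
                f"{want_role} bead"
            )
        ids.append(int(cand[0]))
    return BeadSelection(
        bead_ids=np.asarray(ids, dtype=np.int64),
        provenance=f"reference beads of {len(ids)} residues",
    )


def expand_residue_set(
    topology: BeadTopology, residue_sets: dict[str, list[int]]
) -> list[tuple[int, int, str, int]]:
    """Expand per-species residue lists to all subunit instances.

    ``residue_sets`` maps species (``PHB1``/``PHB2``) to residue_seq lists.
    Returns ordered ``(molecule_id, residue_seq, species, subunit_index)``
    tuples, where subunit_index counts protein subunits in topology order.
    """
    out: list[tuple[int, int, str, int]] = []
    for k, (mol, sp) in enumerate(topology.protein_subunits()):
        for seq in residue_sets.get(sp, []):
            out.append((mol, seq, sp, k))
    if not out:
        raise EmptySelectionError(
            f"residue sets {residue_sets} matched no protein subunit"
        )
    return out
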