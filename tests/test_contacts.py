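"""Contact detection vs a brute-force oracle; frequency statistics."""

from __future__ import annotations

import numpy as np
import pytest

import lipidring as lr
from lipidring.contacts import (
    ContactParams,
    ContactSeries,
    compute_contacts,
    interaction_frequency,
    residue_distance_profile,
)
from lipidring.core import Trajectory
from lipidring.geometry import min_image_dist
from lipidring.select import expand_residue_set, residue_reference_beads


@pytest.fixture(scope="module")
def small_system():
    """50 CL + protein ring, 20 frames of random motion."""
    comp = lr.MembraneComposition(upper={"CL": 25, "POPC": 5},
                                  lower={"CL": 25, "POPC": 5})
    ring = lr.RingSpec(n_subunits=4, ring_radius=4.0)
    params = lr.SimulationParams(n_frames=20, box=(18.0, 18.0, 8.0),
                                 cl_attraction_depth=2.0,
                                 invagination_amplitude=0.3, seed=11)
    topo, f0 = lr.build_topology(comp, ring, box=params.box, seed=11)
    traj, _gt = lr.simulate(topo, f0, params, ring=ring)
    lf = lr.assign_leaflets(traj)
    return traj, lf


def oracle_contacts(traj, leaflets, params):
    """All-pairs double-loop contact matrix, written independently."""
    topo = traj.topology
    instances = expand_residue_set(topo, params.residue_sets)
    ref = residue_reference_beads(topo, [(m, s) for m, s, _sp, _k in instances])
    cl_ids = [int(i) for i in np.flatnonzero(
        (topo.species == "CL") & (topo.bead_role == "phosphate"))]
    total = np.zeros((len(instances), traj.n_frames), dtype=bool)
    upper = np.zeros_like(total)
    lower = np.zeros_like(total)
    mol_col = {int(m): k for k, m in enumerate(leaflets.molecule_ids)}
    for f in range(traj.n_frames):
        for a, bead_a in enumerate(ref.bead_ids):
            for bead_b in cl_ids:
                d = float(min_image_dist(traj.xyz[f, bead_a],
                                         traj.xyz[f, bead_b], traj.box))
                if d <= params.cutoff:
                    total[a, f] = True
                    lab = leaflets.labels[f, mol_col[int(topo.molecule_id[bead_b])]]
                    if lab == "upper":
                        upper[a, f] = True
                    else:
                        lower[a, f] = True
    return total, upper, lower


def test_oracle_equivalence(small_system):
    traj, lf = small_system
    params = ContactParams()
    series = compute_contacts(traj, lf, params)
    total, upper, lower = oracle_contacts(traj, lf, params)
    assert np.array_equal(series.total, total)
    assert np.array_equal(series.upper, upper)
    assert np.array_equal(series.lower, lower)


def test_cutoff_rule_one_bead_inside():
    """A CL bead at 0.55 nm triggers contact, one at 0.70 nm alone does not."""
    comp = lr.MembraneComposition(upper={"CL": 1}, lower={"CL": 1})
    ring = lr.RingSpec(n_subunits=2, ring_radius=3.0)
    topo, f0 = lr.build_topology(comp, ring, box=(12.0, 12.0, 8.0), seed=0)
    lt = topo.lipid_table()
    inst = expand_residue_set(topo, ContactParams().residue_sets)
    ref = residue_reference_beads(topo, [(m, s) for m, s, _sp, _k in inst])
    anchor = f0.coords[ref.bead_ids[0]]
    coords = f0.coords.copy()
    # molecule 0 (upper CL): beads at 0.55 and 0.70 nm from residue 0
    up_row = int(np.flatnonzero(lt.leaflet_hint == "upper")[0])
    lo_row = int(np.flatnonzero(lt.leaflet_hint == "lower")[0])
    up_beads = lt.all_phosphates[lt.phosphate_molecule ==
                                 lt.molecule_id[up_row]]
    lo_beads = lt.all_phosphates[lt.phosphate_molecule ==
                                 lt.molecule_id[lo_row]]
    coords[up_beads[0]] = anchor + [0.55, 0, 0]
    coords[up_beads[1]] = anchor + [0.70, 0, 0]
    coords[lo_beads[0]] = anchor + [1.5, 0, 0]
    coords[lo_beads[1]] = anchor + [2.0, 0, 0]
    xyz = np.stack([coords, coords])
    traj = Trajectory(topo, xyz, np.array([0.0, 1.0]), np.asarray(f0.box))
    series = compute_contacts(traj, None,
                              ContactParams(leaflet_resolved=False))
    assert bool(series.total[0, 0]) is True      # 0.55 nm bead inside cutoff
    row1 = series.total[:, 0]
    # residues far from both molecules see no contact
    assert not row1[5:].all()


def test_frequency_arithmetic():
    series = ContactSeries(
        instances=[(0, 4, "PHB1", 0)],
        sampled_frames=np.arange(4),
        total=np.array([[True, True, True, False]]),
    )
    freq = interaction_frequency(series)
    assert freq.total[0] == pytest.approx(0.75)


def test_all_false_series(small_system):
    traj, lf = small_system
    params = ContactParams(cutoff=1e-6)
    series = compute_contacts(traj, lf, params)
    freq = interaction_frequency(series)
    assert np.all(freq.total == 0.0)


def test_frequency_monotone_in_cutoff(small_system):
    traj, lf = small_system
    prev = None
    for cutoff in (0.5, 0.6, 0.7):
        freq = interaction_frequency(
            compute_contacts(traj, lf, ContactParams(cutoff=cutoff)))
        assert np.all(freq.total >= 0) and np.all(freq.total <= 1)
        if prev is not None:
            assert np.all(freq.total >= prev)
        prev = freq.total


def test_leaflet_frequency_bounded_by_total(small_system):
    traj, lf = small_system
    freq = interaction_frequency(compute_contacts(traj, lf, ContactParams()))
    assert np.all(freq.upper <= freq.total + 1e-12)
    assert np.all(freq.lower <= freq.total + 1e-12)
    # union rule: total <= upper + lower
    assert np.all(freq.total <= freq.upper + freq.lower + 1e-12)


def test_stride_consistency(small_system):
    """Direct strided sampling equals subsampling the full series."""
    traj, lf = small_system
    full = compute_contacts(traj, lf, ContactParams(sample_stride=1.0))
    strided = compute_contacts(traj, lf, ContactParams(sample_stride=2.0))
    assert np.array_equal(strided.total, full.total[:, ::2])


def test_tethered_residue_frequencies(desk_bound):
    """Residues holding tethered CL at 0.5 nm stay in contact nearly always;
    the tether distance is inside the 0.6 nm cutoff."""
    traj, gt = desk_bound
    lf = lr.assign_leaflets(traj)
    freq = interaction_frequency(compute_contacts(traj, lf, ContactParams()))
    assert freq.total.max() >= 0.95
    assert freq.total.min() >= 0.0


def test_distance_profile_geometry():
    """A residue 0.7 nm above a phosphate plane (one bead directly beneath)
    puts all its mass in the [0.7, 0.8) bin."""
    comp = lr.MembraneComposition(upper={"POPC": 16}, lower={"POPC": 1})
    ring = lr.RingSpec(n_subunits=2, ring_radius=2.0)
    topo, f0 = lr.build_topology(comp, ring, box=(8.0, 8.0, 8.0), seed=0)
    lt = topo.lipid_table()
    coords = f0.coords.copy()
    inst = expand_residue_set(topo, ContactParams().residue_sets)
    ref = residue_reference_beads(topo, [(m, s) for m, s, _sp, _k in inst])
    # flat plane of upper-leaflet beads at z=2, one directly beneath each ref
    up_rows = np.flatnonzero(lt.leaflet_hint == "upper")
    grid = [(1 + 1.5 * (i % 4), 1 + 1.5 * (i // 4)) for i in range(15)]
    for n, row in enumerate(up_rows):
        bead = lt.first_phosphate[row]
        if n == 0:
            coords[bead] = [coords[ref.bead_ids[0]][0],
                            coords[ref.bead_ids[0]][1], 2.0]
        else:
            coords[bead] = [grid[n - 1][0], grid[n - 1][1], 2.0]
    for i in ref.bead_ids:
        coords[i][2] = 2.7  # all reference beads 0.7 nm above the plane
    lo_row = np.flatnonzero(lt.leaflet_hint == "lower")[0]
    coords[lt.first_phosphate[lo_row]] = [4.0, 4.0, -2.0]
    xyz = coords[None, :, :]
    traj = Trajectory(topo, xyz, np.array([0.0]), np.asarray(f0.box))
    lf = lr.assign_leaflets(traj)
    prof = residue_distance_profile(traj, lf, leaflet="upper",
                                    species=("POPC",))
    nonzero = prof[prof["mean_count"] > 0]
    # minimum distance is bounded below by 0.7 (the plane is 0.7 nm away) and
    # the [0.7, 0.8) bin holds the residues with a bead directly beneath
    assert (nonzero["r_lo"] >= 0.7 - 1e-9).all()
    in_bin = prof[np.isclose(prof["r_lo"], 0.7)]
    assert in_bin["mean_count"].sum() > 0


def test_distance_profile_translation_invariant(small_system):
    traj, lf = small_system
    sub = Trajectory(traj.topology, traj.xyz[:5], traj.time[:5], traj.box)
    sub_lf = lr.LeafletAssignment(lf.molecule_ids, lf.labels[:5])
    base = residue_distance_profile(sub, sub_lf, leaflet="upper")
    shifted_xyz = sub.xyz.copy()
    shifted_xyz[:, :, 0] = (shifted_xyz[:, :, 0] + 3.3) % traj.box[0]
    shifted_xyz[:, :, 1] = (shifted_xyz[:, :, 1] + 1.7) % traj.box[1]
    shifted = Trajectory(traj.topology, shifted_xyz, sub.time, traj.box)
    prof2 = residue_distance_profile(shifted, sub_lf, leaflet="upper")
    assert np.allclose(base["mean_count"], prof2["mean_count"])
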