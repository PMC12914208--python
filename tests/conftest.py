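"""Shared fixtures: seeded desk-scale synthetic runs reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

import lipidring as lr


@pytest.fixture(scope="session")
def desk_free():
    """Desk-scale run with all sorting/deformation off: pure lateral diffusion."""
    traj, gt = lr.generate(
        "desk", seed=0,
        overrides={"cl_attraction_depth": 0.0, "invagination_amplitude": 0.0},
    )
    return traj, gt


@pytest.fixture(scope="session")
def desk_free_leaflets(desk_free):
    traj, _gt = desk_free
    return lr.assign_leaflets(traj)


@pytest.fixture(scope="session")
def desk_bound():
    """Desk-scale run with 30% of cardiolipin tethered 0.5 nm from residues."""
    traj, gt = lr.generate(
        "desk", seed=0,
        overrides={"bound_fraction": 0.3, "bound_distance": 0.5,
                   "invagination_amplitude": 0.0},
    )
    return traj, gt


@pytest.fixture(scope="session")
def desk_invaginated():
    """Desk-scale run with a 1 nm ramped invagination (no CL sorting)."""
    traj, gt = lr.generate(
        "desk", seed=0,
        overrides={"cl_attraction_depth": 0.0, "invagination_amplitude": 1.0},
    )
    return traj, gt


@pytest.fixture(scope="session")
def paper_topology():
    """Full-scale topology (build only; no dynamics)."""
    comp, ring, params = lr.preset("paper_scale", seed=0)
    topo, frame0 = lr.build_topology(comp, ring, box=params.box, seed=0)
    return topo, frame0, comp, ring, params


def make_uniform_gas(n_a: int, n_b: int, n_frames: int, box_len: float,
                     seed: int = 0):
    """Topology + trajectory of uniformly random beads: A = one-bead glycine
    protein subunits, B = single-phosphate POPC lipids.  The ideal-gas
    reference system for RDF normalization tests."""
    from lipidring.core import BeadTopology, Trajectory

    rng = np.random.default_rng(seed)
    n = n_a + n_b
    topo = BeadTopology.from_arrays(
        np.arange(n),
        np.array(["PHB1"] * n_a + ["POPC"] * n_b),
        np.array(["GLY"] * n_a + ["POPC"] * n_b),
        np.array([1] * n_a + [0] * n_b),
        np.array(["backbone"] * n_a + ["phosphate"] * n_b),
        np.array(["none"] * n_a + ["upper"] * n_b),
    )
    xyz = rng.uniform(0, box_len, size=(n_frames, n, 3))
    traj = Trajectory(topo, xyz, np.arange(n_frames, dtype=float),
                      np.full(3, box_len))
    A = lr.BeadSelection(np.arange(n_a), provenance="A gas")
    B = lr.BeadSelection(np.arange(n_a, n), provenance="B gas")
    return traj, A, B
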