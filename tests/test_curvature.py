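"""Height fields, change maps, and depression-depth recovery."""

from __future__ import annotations

import numpy as np
import pytest

import lipidring as lr
from lipidring.core import CoverageError, GeometryError, Trajectory
from lipidring.curvature import (
    depression_depth,
    height_change_map,
    height_field,
)
from lipidring.density import window_presets
from lipidring.enrichment import RingRegion, fit_ring_region


def analytic_depth(A: float, w: float, region: RingRegion,
                   box, cell: float = 0.5, far_factor: float = 1.5,
                   inner_factor: float = 0.5) -> float:
    """Closed-form expectation of the depth estimator on the generator's
    Gaussian surface z = base - A exp(-d^2 / 2 w^2).

    In-ring term: the area average of the Gaussian over the central disk of
    radius r0 = inner_factor * R, which integrates to
    (2 w^2 / r0^2) (1 - exp(-r0^2 / 2 w^2)).  Far-field term: the mean of
    the Gaussian over the cell centres beyond far_factor * R (evaluated on
    the same grid the estimator uses).
    """
    r0 = inner_factor * region.radius
    disk_avg = 2 * w**2 / r0**2 * (1 - np.exp(-(r0**2) / (2 * w**2)))
    nx = int(np.ceil(box[0] / cell))
    ny = int(np.ceil(box[1] / cell))
    cx = (np.arange(nx) + 0.5) * cell - region.center[0]
    cy = (np.arange(ny) + 0.5) * cell - region.center[1]
    dx, dy = np.meshgrid(cx, cy, indexing="ij")
    dx -= box[0] * np.round(dx / box[0])
    dy -= box[1] * np.round(dy / box[1])
    d = np.hypot(dx, dy)
    far = d > far_factor * region.radius
    far_avg = float(np.mean(np.exp(-(d[far] ** 2) / (2 * w**2))))
    return A * (disk_avg - far_avg)


@pytest.fixture(scope="module")
def flat_run():
    traj, gt = lr.generate("desk", seed=0,
                           overrides={"cl_attraction_depth": 0.0,
                                      "invagination_amplitude": 0.0,
                                      "z_noise": 0.0})
    lf = lr.assign_leaflets(traj)
    return traj, gt, lf


def test_flat_leaflet_height(flat_run):
    traj, _gt, lf = flat_run
    hf = height_field(traj, lf, (0, 5), leaflet="upper")
    assert np.allclose(hf.mean_z[hf.mask], 2.0)
    hf_lo = height_field(traj, lf, (0, 5), leaflet="lower")
    assert np.allclose(hf_lo.mean_z[hf_lo.mask], -2.0)


def test_mask_matches_occupancy(flat_run):
    traj, _gt, lf = flat_run
    hf = height_field(traj, lf, (0, 2), leaflet="upper")
    lt = traj.topology.lipid_table()
    cols = np.searchsorted(lf.molecule_ids,
                           traj.topology.molecule_id[lt.all_phosphates])
    occupied = np.zeros_like(hf.mask)
    for f in range(2):
        beads = lt.all_phosphates[lf.labels[f, cols] == "upper"]
        ix = np.floor(traj.xyz[f, beads, 0] / hf.cell).astype(int)
        iy = np.floor(traj.xyz[f, beads, 1] / hf.cell).astype(int)
        occupied[ix, iy] = True
    assert np.array_equal(hf.mask, occupied)


def test_analytic_field_recovery():
    """Dense flat membrane with a known Gaussian dip: occupied cells match
    the analytic surface within the noise budget."""
    comp = lr.MembraneComposition(upper={"POPC": 2000}, lower={"POPC": 200})
    ring = lr.RingSpec()
    params = lr.SimulationParams(n_frames=10, z_noise=0.05,
                                 cl_attraction_depth=0.0,
                                 invagination_amplitude=0.8, ramp=0.1,
                                 seed=2)
    topo, f0 = lr.build_topology(comp, ring, box=params.box, seed=2)
    traj, _gt = lr.simulate(topo, f0, params, ring=ring)
    lf = lr.assign_leaflets(traj)
    hf = height_field(traj, lf, (5, 10), leaflet="upper")  # post-ramp frames
    cx, cy = hf.cell_centers()
    d = np.hypot(cx - 18.0, cy - 18.0)
    analytic = 2.0 - 0.8 * np.exp(-(d**2) / (2 * 5.0**2))
    err = np.abs(hf.mean_z - analytic)[hf.mask]
    # cell-centre offset (<= cell/sqrt(2)) on the max gradient plus z noise
    assert np.percentile(err, 95) < 0.12
    assert err.mean() < 0.05


def test_static_change_map_identically_zero(flat_run):
    """A static trajectory (no diffusion, no noise, no ramp) has an exactly
    zero height-change map."""
    comp = lr.MembraneComposition(upper={"POPC": 50}, lower={"POPC": 50})
    params = lr.SimulationParams(
        n_frames=40, z_noise=0.0, cl_attraction_depth=0.0,
        invagination_amplitude=0.0,
        diffusion={"POPC": 0.0, "POPE": 0.0, "CL": 0.0}, seed=0)
    topo, f0 = lr.build_topology(comp, lr.RingSpec(), box=params.box, seed=0)
    traj, _gt = lr.simulate(topo, f0, params, ring=lr.RingSpec())
    lf = lr.assign_leaflets(traj)
    delta, mask = height_change_map(traj, lf, leaflet="upper")
    assert np.all(delta[mask] == 0.0)


def test_change_map_antisymmetry(desk_invaginated):
    traj, _gt = desk_invaginated
    lf = lr.assign_leaflets(traj)
    wins = window_presets(traj)
    fwd, m1 = height_change_map(traj, lf, windows=wins)
    swapped = {"initial": wins["final"], "final": wins["initial"]}
    rev, m2 = height_change_map(traj, lf, windows=swapped)
    assert np.array_equal(m1, m2)
    assert np.allclose(fwd[m1], -rev[m2])


def test_change_map_most_negative_inside_ring(desk_invaginated):
    traj, gt = desk_invaginated
    lf = lr.assign_leaflets(traj)
    delta, mask = height_change_map(traj, lf, leaflet="upper")
    region = fit_ring_region(traj.topology, traj.frame(0))
    nx, ny = delta.shape
    cx = (np.arange(nx) + 0.5) * 0.5 - region.center[0]
    cy = (np.arange(ny) + 0.5) * 0.5 - region.center[1]
    d = np.hypot(*np.meshgrid(cx, cy, indexing="ij"))
    vals = delta[mask]
    dist = d[mask]
    deepest = np.argsort(vals)[:10]
    assert np.median(dist[deepest]) <= region.radius


def test_depth_zero_for_flat_field(flat_run):
    traj, _gt, lf = flat_run
    wins = window_presets(traj)
    fi = height_field(traj, lf, wins["initial"])
    ff = height_field(traj, lf, wins["final"])
    region = fit_ring_region(traj.topology, traj.frame(0))
    dep = depression_depth(fi, ff, region)
    assert dep.depth == pytest.approx(0.0, abs=1e-9)
    assert dep.depth_min == pytest.approx(0.0, abs=1e-9)


def test_depth_recovery_and_monotonicity():
    """Across increasing invagination amplitudes the estimated depth is
    monotone and within 0.1 nm of the analytic disk-average; doubling the
    amplitude doubles the depth within the same budget."""
    depths = []
    for A in (0.0, 0.35, 0.7):
        traj, _gt = lr.generate("desk", seed=0,
                                overrides={"invagination_amplitude": A,
                                           "cl_attraction_depth": 0.0})
        lf = lr.assign_leaflets(traj)
        region = fit_ring_region(traj.topology, traj.frame(0))
        wins = window_presets(traj)
        fi = height_field(traj, lf, wins["initial"])
        ff = height_field(traj, lf, wins["final"])
        dep = depression_depth(fi, ff, region)
        expected = analytic_depth(A, 5.0, region, traj.box)
        assert dep.depth == pytest.approx(expected, abs=0.1)
        depths.append(dep.depth)
    assert depths[0] < depths[1] < depths[2]
    assert depths[2] == pytest.approx(2 * depths[1], abs=0.1)


def test_depth_invariant_under_global_shift(desk_invaginated):
    traj, _gt = desk_invaginated
    lf = lr.assign_leaflets(traj)
    region = fit_ring_region(traj.topology, traj.frame(0))
    wins = window_presets(traj)
    fi = height_field(traj, lf, wins["initial"])
    ff = height_field(traj, lf, wins["final"])
    dep = depression_depth(fi, ff, region)
    shifted = Trajectory(traj.topology, traj.xyz + np.array([0, 0, 5.0]),
                         traj.time, traj.box)
    lf2 = lr.assign_leaflets(shifted)
    fi2 = height_field(shifted, lf2, wins["initial"])
    ff2 = height_field(shifted, lf2, wins["final"])
    dep2 = depression_depth(fi2, ff2, region)
    assert dep2.depth == pytest.approx(dep.depth, abs=1e-9)
    assert dep2.depth_min == pytest.approx(dep.depth_min, abs=1e-9)


def test_no_far_field_raises(flat_run):
    traj, _gt, lf = flat_run
    wins = window_presets(traj)
    fi = height_field(traj, lf, wins["initial"])
    ff = height_field(traj, lf, wins["final"])
    huge = RingRegion(center=(18.0, 18.0), radius=30.0)
    with pytest.raises(GeometryError):
        depression_depth(fi, ff, huge)
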