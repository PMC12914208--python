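"""Stage orchestration: one reproducible run from config to tidy outputs.

Stages execute in dependency order — generate/load, leaflet assignment, then
the independent analyses (RDF, density maps, contacts, ring enrichment) and
finally curvature — and every output is a deterministic CSV/JSON file listed
in the run manifest.  Identical (config, seed) pairs produce byte-identical
analysis outputs.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as lio
from .config import PipelineConfig
from .contacts import ContactParams, compute_contacts, interaction_frequency
from .core import LipidRingError, Trajectory
from .curvature import depression_depth, height_change_map, height_field
from .density import DensityParams, compute_density_map, window_presets
from .enrichment import count_in_region, enrichment_ratio, fit_ring_region
from .leaflets import assign_leaflets
from .rdf import RDFParams, compute_rdf, peak_location
from .select import residue_reference_beads, expand_residue_set, select_beads
from .synthetic import (
    GroundTruthManifest,
    SimulationParams,
    build_topology,
    preset,
    simulate,
)

log = logging.getLogger("lipidring")


class StageError(LipidRingError):
    """An analysis stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: Exception,
                 partial_outputs: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_outputs = partial_outputs


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages_run: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    wall_time_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config,
            "seed": self.seed,
            "stages_run": self.stages_run,
            "outputs": sorted(self.outputs),
            "wall_time_s": self.wall_time_s,
        }, indent=1))


def _load_or_generate(config: PipelineConfig):
    if config.preset is not None:
        comp, ring, params = preset(config.preset, seed=config.seed)
        gen = {k: v for k, v in config["generator"].items() if v is not None}
        for k, v in gen.items():
            setattr(params, k, v)
        params.seed = config.seed
        params.__post_init__()
        topo, frame0 = build_topology(comp, ring, box=params.box,
                                      seed=config.seed)
        traj, manifest = simulate(topo, frame0, params, ring=ring)
        return traj, manifest, ring
    topo, _frame0 = lio.read_topology(config["input"]["topology"])
    traj = lio.read_trajectory(config["input"]["trajectory"], topo)
    return traj, None, None


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.blocks, seed=config.seed)
    stages = config["stages"]

    def _run(stage: str, fn):
        t0 = _time.perf_counter()
        try:
            fn()
        except Exception as e:
            raise StageError(stage, e, list(manifest.outputs)) from e
        manifest.stages_run.append(stage)
        manifest.wall_time_s[stage] = round(_time.perf_counter() - t0, 3)
        log.info("stage %s done (%.2fs)", stage, manifest.wall_time_s[stage])

    def _emit(name: str) -> Path:
        manifest.outputs.append(name)
        return out_dir / name

    state: dict = {}

    def stage_generate():
        traj, gt, ring = _load_or_generate(config)
        state["traj"], state["gt"], state["ring"] = traj, gt, ring
        if gt is not None:
            gt.to_json(_emit("ground_truth_manifest.json"))
        lio.write_topology(traj.topology, traj.frame(0),
                           _emit("topology.json"), format="JSON")

    def stage_leaflets():
        lf = assign_leaflets(state["traj"],
                             radius=config["leaflets"]["radius"],
                             min_neighbors=config["leaflets"]["min_neighbors"])
        state["leaflets"] = lf
        if stages["leaflets"]:
            lf.to_csv(_emit("leaflets.csv"))

    def stage_region():
        traj = state["traj"]
        region = fit_ring_region(traj.topology, traj.frame(0),
                                 margin=config["enrichment"]["margin"])
        state["region"] = region

    def stage_rdf():
        traj = state["traj"]
        p = config["rdf"]
        instances = expand_residue_set(
            traj.topology, ContactParams().residue_sets)
        A = residue_reference_beads(
            traj.topology, [(m, s) for m, s, _sp, _k in instances])
        params = RDFParams(
            r_max=p["r_max"], bin_width=p["bin_width"], leaflet=p["leaflet"],
            shell_normalization=p["shell_normalization"],
            cl_single_bead=p["cl_single_bead"])
        for sp in ("CL", "POPC", "POPE"):
            B = select_beads(traj.topology, species=sp, role="phosphate")
            res = compute_rdf(traj, A, B, state["leaflets"], params)
            res.to_csv(_emit(f"rdf_{sp}_{p['leaflet']}.csv"))
            if sp == "CL":
                try:
                    state["rdf_peak"] = peak_location(res)
                except LipidRingError:
                    state["rdf_peak"] = None

    def stage_density():
        traj = state["traj"]
        p = config["density"]
        wins = window_presets(traj)
        for wname, win in wins.items():
            for sp in ("CL", "PC+PE"):
                dm = compute_density_map(traj, state["leaflets"], DensityParams(
                    cell=p["cell"], window=win, leaflet=p["leaflet"],
                    species=sp))
                tag = sp.replace("+", "")
                dm.to_csv(_emit(f"density_{tag}_{p['leaflet']}_{wname}.csv"))

    def stage_contacts():
        traj = state["traj"]
        p = config["contacts"]
        series = compute_contacts(traj, state["leaflets"], ContactParams(
            cutoff=p["cutoff"], sample_stride=p["sample_stride"]))
        freq = interaction_frequency(series)
        freq.to_csv(_emit("contact_frequency.csv"))

    def stage_enrichment():
        traj = state["traj"]
        series = count_in_region(traj, state["leaflets"], state["region"])
        df = enrichment_ratio(series, traj.box)
        df.to_csv(_emit("enrichment_timeseries.csv"), index=False,
                  float_format="%.6f")

    def stage_curvature():
        traj = state["traj"]
        p = config["curvature"]
        wins = window_presets(traj)
        fi = height_field(traj, state["leaflets"], wins["initial"],
                          p["leaflet"], p["cell"], smooth=p["smooth"])
        ff = height_field(traj, state["leaflets"], wins["final"],
                          p["leaflet"], p["cell"], smooth=p["smooth"])
        delta, _mask = height_change_map(traj, state["leaflets"], p["leaflet"],
                                         p["cell"], windows=wins)
        np.savetxt(_emit(f"height_change_{p['leaflet']}.csv"), delta,
                   delimiter=",", fmt="%.8g")
        dep = depression_depth(fi, ff, state["region"])
        dep.to_json(_emit(f"depression_{p['leaflet']}.json"))

    log.info("run: seed=%d preset=%s out=%s", config.seed, config.preset,
             out_dir)
    if not any(stages.values()):
        manifest.to_json(out_dir / "run_manifest.json")
        return manifest
    _run("generate", stage_generate)
    _run("leaflets", stage_leaflets)
    need_region = stages["enrichment"] or stages["curvature"]
    if need_region:
        _run("region", stage_region)
    if stages["rdf"]:
        _run("rdf", stage_rdf)
    if stages["density"]:
        _run("density", stage_density)
    if stages["contacts"]:
        _run("contacts", stage_contacts)
    if stages["enrichment"]:
        _run("enrichment", stage_enrichment)
    if stages["curvature"]:
        _run("curvature", stage_curvature)

    manifest.to_json(out_dir / "run_manifest.json")
    return manifest
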