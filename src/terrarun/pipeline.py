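"""End-to-end orchestration: simulate, analyse, compare, report.

A :class:`PipelineConfig` bundles the terrain spec, gait spec, subject
parameters, stepping-model configuration and processing settings. A
single global seed deterministically spawns per-stage seeds (logged in
the report) so stages can be re-run in isolation and identical
(config, seed) pairs give identical outputs.

``run_pipeline`` executes, in order: terrain generation, trial
simulation, marker kinematics, force-plate kinetics, collision-model
predictions per step, the stepping-scheme comparison and placement
index, and energetics — and writes every table as tidy CSV plus a JSON
run report carrying provenance (config hash, spawned seeds, package
version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collision import (
    SubjectParams,
    build_chain,
    compliant_collision,
    rigid_collision,
    state_from_landing,
)
from .energetics import net_metabolic_rate
from .errors import TerrarunError, ValidationError
from .footsteps import (
    DirectedWalkConfig,
    PatchStatTable,
    StepSequence,
    compare_schemes,
    foot_placement_index,
)
from .kinematics import (
    align_track_frame,
    detect_stance_events,
    per_step_metrics,
    trial_summary,
)
from .kinetics import detect_force_touchdown, filter_forces, fore_aft_impulse
from .synthetic import (
    GaitSpec,
    TerrainSpec,
    generate_respirometry,
    generate_terrain,
    generate_trial,
    terrain_spec,
)
from .terrain import build_cell_grid

log = logging.getLogger("terrarun")


@dataclass
class PipelineConfig:
    """Validated configuration of one end-to-end run."""

    terrain_class: str = "uneven2"
    terrain: dict = field(default_factory=dict)       # TerrainSpec overrides
    gait: dict = field(default_factory=dict)          # GaitSpec overrides
    subject: dict = field(default_factory=dict)       # SubjectParams overrides
    walk: dict = field(default_factory=dict)          # DirectedWalkConfig overrides
    n_walk_steps: int = 10_000
    n_blind: int = 10_000
    resting_power: float = 90.0                       # W
    running_power_net: float = 13.1                   # W/kg net target
    filter_cutoff: float = 270.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Paths and provenance of everything one pipeline run produced."""

    outdir: Path
    config_hash: str
    seeds: dict
    tables: dict
    summary: dict


def _spawned_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    names = ["terrain", "trial", "walk", "blind", "respirometry"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute every stage and write all result tables.

    Any stage failure aborts with the stage name prefixed to the error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawned_seeds(config.seed)
    subject = SubjectParams(**config.subject)
    tables = {}
    summary = {"terrain_class": config.terrain_class}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except TerrarunError as exc:
            raise TerrarunError(
                f"pipeline stage '{name}' failed (config "
                f"{config.config_hash()}): {exc}"
            ) from exc

    # --- terrain -----------------------------------------------------------
    tspec = terrain_spec(config.terrain_class, seed=seeds["terrain"],
                         **config.terrain)
    field_ = stage("terrain", generate_terrain, tspec)

    # --- trial -------------------------------------------------------------
    gait = GaitSpec(seed=seeds["trial"], body_mass=subject.body_mass,
                    leg_length=subject.leg_length,
                    foot_length=subject.foot_length, **config.gait)
    markers, forces, truth = stage("trial", generate_trial, gait, field_)

    # --- kinematics --------------------------------------------------------
    aligned = stage("kinematics", align_track_frame, markers)
    events = stage("kinematics", detect_stance_events, aligned, subject)
    series = stage("kinematics", per_step_metrics, aligned, events, subject)
    steps = series.to_frame()
    steps.insert(0, "trial", 0)
    steps.insert(1, "terrain_class", config.terrain_class)
    tables["steps"] = steps
    summary_frame = stage("kinematics", trial_summary, series, subject)
    tables["trial_summary"] = summary_frame.reset_index()

    # --- kinetics ----------------------------------------------------------
    filtered = stage("kinetics", filter_forces, forces,
                     cutoff=config.filter_cutoff)
    stances = stage("kinetics", detect_force_touchdown, filtered)
    impulse_rows = []
    for sid, stance in enumerate(stances):
        # direction & flight speed from the matching kinematic step
        rec = min(series.records, key=lambda r: abs(r.touchdown_time - stance[0]))
        vy = rec.com_speed if np.isfinite(rec.com_speed) else gait.speed
        imp = fore_aft_impulse(filtered, stance, vy, subject.body_mass,
                               direction=rec.direction, step_id=sid)
        impulse_rows.append({
            "step_id": sid, "touchdown": stance[0], "liftoff": stance[1],
            "jy_star": imp.jy_star,
            "aerial_momentum": imp.aerial_momentum,
            "normalized_impulse": imp.normalized_impulse,
        })
    tables["impulses"] = pd.DataFrame(impulse_rows)
    if impulse_rows:
        summary["mean_normalized_impulse"] = float(
            tables["impulses"]["normalized_impulse"].mean())

    # --- collision predictions per step ------------------------------------
    coll_rows = []
    for k, rec in enumerate(series.records):
        if not (np.isfinite(rec.foot_speed_froude)
                and np.isfinite(rec.com_speed)
                and np.isfinite(rec.leg_angle_td)):
            continue
        chain = build_chain(subject, rec.leg_angle_td,
                            touchdown_leg_length=rec.leg_length_td
                            if np.isfinite(rec.leg_length_td) else None)
        vz = rec.com_landing_velocity[2]
        state = state_from_landing(
            chain, rec.com_speed,
            abs(vz) if np.isfinite(vz) else 0.7,
            rec.foot_speed_froude, subject)
        coll_rows.append({
            "step": k,
            "foot_speed_froude": rec.foot_speed_froude,
            "rigid": rigid_collision(chain, state).normalized_impulse,
            "compliant": compliant_collision(chain, state).normalized_impulse,
        })
    tables["collision_predictions"] = pd.DataFrame(coll_rows)

    # --- stepping schemes and placement index ------------------------------
    observed = StepSequence(
        positions=truth.footsteps,
        directions=truth.directions,
        h_iqr=np.zeros(len(truth.footsteps)),
        h_median=np.zeros(len(truth.footsteps)),
    )
    walk_kwargs = dict(config.walk)
    walk_kwargs.setdefault("n_steps", config.n_walk_steps)
    wcfg = DirectedWalkConfig(seed=seeds["walk"], **walk_kwargs)
    table = PatchStatTable(field_, wcfg.patch_size)
    observed.h_iqr = table.iqr_at(truth.footsteps[:, 0], truth.footsteps[:, 1])
    observed.h_median = table.median_at(truth.footsteps[:, 0],
                                        truth.footsteps[:, 1])
    scheme_summary, scheme_hist = stage(
        "stepmodel", compare_schemes, field_, observed, wcfg,
        n_blind=config.n_blind, seed=seeds["blind"], table=table)
    tables["scheme_comparison"] = scheme_summary.reset_index()
    tables["scheme_histograms"] = scheme_hist

    grid = build_cell_grid(field_, subject.foot_length)
    pim = stage("stepmodel", foot_placement_index, grid, truth.footsteps,
                gait.step_length_mean)
    tables["placement_index"] = pim.to_frame(grid)

    # --- energetics ---------------------------------------------------------
    respiro = stage(
        "energetics", generate_respirometry,
        config.resting_power,
        config.resting_power + config.running_power_net * subject.body_mass,
        seed=seeds["respirometry"])
    met = stage("energetics", net_metabolic_rate, respiro, subject.body_mass)
    summary["net_metabolic_rate_w_per_kg"] = met.net_rate
    summary["metabolic_plateau"] = met.plateau_reached
    summary["n_steps_detected"] = len(series.records)
    summary["n_turnarounds"] = int(truth.n_turnarounds)

    # --- write everything ---------------------------------------------------
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    report = RunReport(
        outdir=outdir,
        config_hash=config.config_hash(),
        seeds=seeds,
        tables={k: f"{k}.csv" for k in tables},
        summary=summary,
    )
    (outdir / "report.json").write_text(json.dumps({
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": report.config_hash,
        "seeds": seeds,
        "tables": report.tables,
        "summary": summary,
    }, indent=1, default=float))
    return report
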