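"""End-to-end orchestration: synthesize -> process -> classify -> simulate
-> compare, with a saved configuration sufficient to reproduce the run.

``run_end_to_end`` executes all stages in order into a run directory and
writes a manifest (config echo, seeds, per-file SHA-256 hashes);
``report_summary`` re-reads the persisted artefacts and emits a JSON +
markdown summary whose every number is re-derivable from those files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chains as chains_mod
from . import io as io_mod
from . import placecells, plateau, signals, synth

logger = logging.getLogger("plateaulearn")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Serializable configuration of one end-to-end run.

    Defaults are the study conditions: a 60-lap environment-A session,
    200 CA1 units with 40% place cells, 2000 chains, 10000 model neurons,
    100 SI shuffles, merge threshold 0.45 and a 20-25% recruitment band.
    """

    environment: str = "A"
    seed: int = 0
    n_laps: int = 60
    n_cells: int = 200
    frac_place: float = 0.4
    n_shuffles: int = 100
    merge_threshold: float = 0.45
    n_ec3_axons_imaged: int = 200       # chains sampled for the axonal ROI field of view
    n_chains: int = 2000
    n_neurons: int = 10000
    n_inputs: int = 100
    inhibition_scale: float = 0.05
    recruit_band: tuple = (0.20, 0.25)
    enhanced_tuning: bool = False
    zone_halfwidth_cm: float = 18.0
    out_dir: str = "run"
    verbosity: str = "INFO"
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        if "recruit_band" in raw:
            raw["recruit_band"] = tuple(raw["recruit_band"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["recruit_band"] = list(d["recruit_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: behaviour -> CA1 traces/maps -> place-cell classification
    -> EC3 chains (+ axonal ROIs and merging) -> plateau model -> profile
    comparison.  Completed-stage outputs are left intact on a later-stage
    failure; errors carry the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    config.to_yaml(out / "config.yaml")
    written: list[Path] = [out / "config.yaml"]
    stage = "init"
    try:
        stage = "synth"
        logger.info("stage %s: environment %s, %d laps, seed %d",
                    stage, config.environment, config.n_laps, config.seed)
        behavior = synth.generate_behavior(config.n_laps, config.environment,
                                           seed=config.seed)
        ca1_traces, truth = synth.generate_ca1_traces(
            behavior, n_cells=config.n_cells, frac_place=config.frac_place,
            seed=config.seed + 1)

        stage = "signal_processing"
        ca1_traces = signals.compute_dff(ca1_traces)
        ca1_maps = signals.build_activity_map(ca1_traces, behavior)
        io_mod.save_session(out / "session.h5", behavior=behavior,
                            traces=ca1_traces, ground_truth=truth, maps=ca1_maps)
        io_mod.activity_map_to_csv(ca1_maps, out / "ca1_maps.csv")
        written += [out / "session.h5", out / "session.behavior.csv",
                    out / "ca1_maps.csv"]

        stage = "place_cells"
        records = placecells.classify_place_cells(
            ca1_maps, ca1_traces, behavior, n_shuffles=config.n_shuffles,
            seed=config.seed + 2)
        rec_out = records.drop(columns=["field_bins"])
        rec_out.to_csv(out / "place_field_records.csv", index=False)
        written.append(out / "place_field_records.csv")

        stage = "ec3_chains"
        cfg = chains_mod.build_config(
            config.environment if config.environment in ("A", "B") else "uniform",
            overrides={"n_chains": config.n_chains,
                       "enhanced_tuning": config.enhanced_tuning})
        population = chains_mod.simulate_chains(cfg, seed=config.seed + 3)
        maps3 = chains_mod.map_time_to_space(population)
        bm = signals.behavior_maps(behavior)
        metrics = chains_mod.chain_metrics(maps3, velocity_map=bm.velocity)
        metrics.to_csv(out / "chain_metrics.csv", index=False)
        written.append(out / "chain_metrics.csv")

        stage = "ec3_rois"
        rng = np.random.default_rng(config.seed + 4)
        subset = np.sort(rng.choice(cfg.n_chains, size=config.n_ec3_axons_imaged,
                                    replace=False))
        fov = chains_mod.ChainPopulation(states=population.states[subset],
                                         config=dataclasses.replace(
                                             cfg, n_chains=subset.size,
                                             boost_p01=cfg.boost_p01[subset],
                                             phase_step=cfg.phase_step[subset]))
        ec3_traces, ec3_truth = synth.generate_ec3_rois(fov, behavior,
                                                        seed=config.seed + 5)
        ec3_traces = signals.compute_dff(ec3_traces)
        grouping = signals.merge_rois_by_noise_correlation(
            ec3_traces, threshold=config.merge_threshold)
        pd.DataFrame({"roi": np.arange(ec3_traces.n_rois),
                      "axon": grouping.roi_to_axon,
                      "true_axon": ec3_truth.axon_id}).to_csv(
            out / "axon_grouping.csv", index=False)
        written.append(out / "axon_grouping.csv")

        stage = "plateau_model"
        drives = plateau.simulate_population_drive(
            population, n_neurons=config.n_neurons, n_inputs=config.n_inputs,
            inhibition_scale=config.inhibition_scale, seed=config.seed + 6)
        threshold, recruited = plateau.calibrate_threshold(
            drives, target_band=tuple(config.recruit_band))
        dwell = behavior.dwell_profile(n_bins=50)
        mapping = chains_mod.SpaceMapping.from_dwell(
            dwell, steps_per_lap=cfg.steps_per_lap, dt=cfg.dt)
        result = plateau.crossing_profile(drives, threshold, mapping, population,
                                          recruited_fraction=recruited)

        stage = "compare"
        pc = records[records["is_place_cell"]]
        density = np.bincount(pc["peak_bin"].to_numpy(),
                              minlength=ca1_maps.n_bins).astype(float)
        zone = chains_mod.zone_bins(behavior.reward_position,
                                    config.zone_halfwidth_cm)
        comparison = plateau.compare_profiles(result.crossing_profile, density,
                                              zone=zone) \
            if len(pc) else {"r": float("nan"), "degenerate": True}
        plateau_out = dict(
            threshold=result.threshold,
            recruited_fraction=result.recruited_fraction,
            crossing_profile=result.crossing_profile.tolist(),
            crossing_profile_constant_speed=
                result.crossing_profile_constant_speed.tolist(),
            n_model_neurons=result.n_model_neurons,
            comparison={k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in comparison.items()},
            place_cell_density=density.tolist())
        (out / "plateau.json").write_text(json.dumps(plateau_out, indent=1))
        written.append(out / "plateau.json")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed with config {config}") from exc
    finally:
        logger.removeHandler(fh)
        fh.close()

    manifest = dict(schema_version=SCHEMA_VERSION, seed=config.seed,
                    environment=config.environment,
                    cue_position=-1.0 if behavior.cue_position is None
                    else behavior.cue_position,
                    files={p.name: _sha256(p) for p in written if p.exists()})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report_summary(run_dir) -> dict:
    """Human-readable summary recomputed from the persisted artefacts."""
    run_dir = Path(run_dir)
    missing = [n for n in ("place_field_records.csv", "plateau.json",
                           "chain_metrics.csv", "session.h5")
               if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing artefacts: {missing}")
    records = pd.read_csv(run_dir / "place_field_records.csv")
    plateau_out = json.loads((run_dir / "plateau.json").read_text())
    metrics = pd.read_csv(run_dir / "chain_metrics.csv")

    pc = records[records["is_place_cell"]]
    summary: dict = {
        "n_units": int(len(records)),
        "n_place_cells": int(len(pc)),
        "recruited_fraction": plateau_out["recruited_fraction"],
        "chain_median_odd_even_r": float(metrics["odd_even_r"].median()),
        "chain_frac_well_correlated": float(metrics["well_correlated"].mean()),
        "model_data_r": plateau_out["comparison"].get("r"),
    }
    if len(pc):
        summary["peak_shift_median_cm"] = float(pc["peak_shift"].median())
        summary["reliability_mean"] = float(pc["reliability"].mean())
        prof = np.asarray(plateau_out["crossing_profile"])
        summary["plateau_zone_enrichment"] = plateau_out["comparison"].get(
            "model_zone_enrichment",
            float(prof.max() / prof.mean()) if prof.mean() > 0 else float("nan"))
    else:
        summary["note"] = "no place cells detected; plasticity-signature stats skipped"

    lines = ["| quantity | value |", "| --- | --- |"]
    for k, v in summary.items():
        lines.append(f"| {k} | {v if not isinstance(v, float) else round(v, 4)} |")
    (run_dir / "summary.md").write_text("\n".join(lines) + "\n")
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
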