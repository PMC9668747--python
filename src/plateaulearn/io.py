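"""HDF5 session container and CSV sidecars.

Layout of the session container::

    /behavior       time_s, position_cm, velocity_cms, lick, lap_index
                    attrs: reward_position, cue_position, belt_length,
                    environment, frame_rate
    /traces         F, dff (optional), roi_size
                    attrs: frame_rate, modality
    /ground_truth   cell_class, true_induction_lap, true_field_center,
                    true_field_width, induction_velocity, axon_id (optional)
    /maps           mean_dff, occupancy, significant, valid_laps
                    attrs: reward_bin, rotation_shift, environment

A flat CSV behaviour log (time_s, position_cm, velocity_cms, lick,
lap_index) is written alongside for interoperability.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signals import ActivityMap
from .synth import BehaviorSession, GroundTruth, RoiTraceSet


def save_behavior(h5: h5py.File, behavior: BehaviorSession) -> None:
    g = h5.require_group("behavior")
    for name, arr in [("time_s", behavior.time), ("position_cm", behavior.position),
                      ("velocity_cms", behavior.velocity),
                      ("lick", behavior.lick.astype(np.uint8)),
                      ("lap_index", behavior.lap_index)]:
        if name in g:
            del g[name]
        g.create_dataset(name, data=arr)
    g.attrs["reward_position"] = behavior.reward_position
    g.attrs["cue_position"] = -1.0 if behavior.cue_position is None else behavior.cue_position
    g.attrs["belt_length"] = behavior.belt_length
    g.attrs["environment"] = behavior.environment
    g.attrs["frame_rate"] = behavior.frame_rate


def load_behavior(h5: h5py.File) -> BehaviorSession:
    g = h5["behavior"]
    cue = float(g.attrs["cue_position"])
    return BehaviorSession(
        time=g["time_s"][:], position=g["position_cm"][:],
        velocity=g["velocity_cms"][:], lick=g["lick"][:].astype(bool),
        lap_index=g["lap_index"][:].astype(int),
        reward_position=float(g.attrs["reward_position"]),
        cue_position=None if cue < 0 else cue,
        belt_length=float(g.attrs["belt_length"]),
        environment=str(g.attrs["environment"]),
        frame_rate=float(g.attrs["frame_rate"]))


def save_traces(h5: h5py.File, traces: RoiTraceSet, group: str = "traces") -> None:
    g = h5.require_group(group)
    for name in ("F", "dff", "roi_size"):
        if name in g:
            del g[name]
    g.create_dataset("F", data=traces.F)
    if traces.dff is not None:
        g.create_dataset("dff", data=traces.dff)
    g.create_dataset("roi_size", data=traces.roi_size)
    g.attrs["frame_rate"] = traces.frame_rate
    g.attrs["modality"] = traces.modality


def load_traces(h5: h5py.File, group: str = "traces") -> RoiTraceSet:
    g = h5[group]
    return RoiTraceSet(F=g["F"][:], roi_size=g["roi_size"][:],
                       frame_rate=float(g.attrs["frame_rate"]),
                       modality=str(g.attrs["modality"]),
                       dff=g["dff"][:] if "dff" in g else None)


def save_ground_truth(h5: h5py.File, truth: GroundTruth) -> None:
    g = h5.require_group("ground_truth")
    for k in list(g.keys()):
        del g[k]
    g.create_dataset("cell_class", data=truth.cell_class.astype("S"))
    g.create_dataset("true_induction_lap", data=truth.true_induction_lap)
    g.create_dataset("true_field_center", data=truth.true_field_center)
    g.create_dataset("true_field_width", data=truth.true_field_width)
    g.create_dataset("induction_velocity", data=truth.induction_velocity)
    if truth.axon_id is not None:
        g.create_dataset("axon_id", data=truth.axon_id)


def load_ground_truth(h5: h5py.File) -> GroundTruth:
    g = h5["ground_truth"]
    return GroundTruth(
        cell_class=g["cell_class"][:].astype(str),
        true_induction_lap=g["true_induction_lap"][:],
        true_field_center=g["true_field_center"][:],
        true_field_width=g["true_field_width"][:],
        induction_velocity=g["induction_velocity"][:],
        axon_id=g["axon_id"][:] if "axon_id" in g else None)


def save_activity_map(h5: h5py.File, maps: ActivityMap, group: str = "maps") -> None:
    g = h5.require_group(group)
    for k in list(g.keys()):
        del g[k]
    g.create_dataset("mean_dff", data=maps.mean_dff)
    g.create_dataset("occupancy", data=maps.occupancy)
    g.create_dataset("significant", data=maps.significant.astype(np.uint8))
    g.create_dataset("valid_laps", data=maps.valid_laps.astype(np.uint8))
    g.attrs["reward_bin"] = maps.reward_bin
    g.attrs["rotation_shift"] = maps.rotation_shift
    g.attrs["environment"] = maps.environment


def load_activity_map(h5: h5py.File, group: str = "maps") -> ActivityMap:
    g = h5[group]
    m = g["mean_dff"][:]
    return ActivityMap(mean_dff=m, occupancy=g["occupancy"][:],
                       significant=g["significant"][:].astype(bool),
                       valid_laps=g["valid_laps"][:].astype(bool),
                       reward_bin=int(g.attrs["reward_bin"]),
                       rotation_shift=int(g.attrs["rotation_shift"]),
                       environment=str(g.attrs["environment"]),
                       n_bins=m.shape[2], bin_width=180.0 / m.shape[2])


def behavior_to_csv(behavior: BehaviorSession, path) -> None:
    pd.DataFrame({"time_s": behavior.time, "position_cm": behavior.position,
                  "velocity_cms": behavior.velocity,
                  "lick": behavior.lick.astype(int),
                  "lap_index": behavior.lap_index}).to_csv(path, index=False)


def activity_map_to_csv(maps: ActivityMap, path) -> None:
    """Flat (unit, lap, bin, mean_dff) table."""
    u, l, b = np.meshgrid(np.arange(maps.n_units), np.arange(maps.n_laps),
                          np.arange(maps.n_bins), indexing="ij")
    pd.DataFrame({"unit": u.ravel(), "lap": l.ravel(), "bin": b.ravel(),
                  "mean_dff": maps.mean_dff.ravel()}).to_csv(path, index=False)


def save_session(path, behavior: BehaviorSession | None = None,
                 traces: RoiTraceSet | None = None,
                 ground_truth: GroundTruth | None = None,
                 maps: ActivityMap | None = None,
                 csv_sidecar: bool = True) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        if behavior is not None:
            save_behavior(h5, behavior)
        if traces is not None:
            save_traces(h5, traces)
        if ground_truth is not None:
            save_ground_truth(h5, ground_truth)
        if maps is not None:
            save_activity_map(h5, maps)
    if behavior is not None and csv_sidecar:
        behavior_to_csv(behavior, path.with_suffix(".behavior.csv"))
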