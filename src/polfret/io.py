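"""Readers and writers for the package's on-disk formats.

Traces travel as long-format CSV (molecule_id, frame, time_s, DD, DA) or
HDF5 (one group per molecule with DD/DA datasets; frame_dt and t_add as
attributes).  Ground-truth state paths are JSON sidecars; events and
dwells are flat CSV tables; simulator configurations are YAML mirroring
the KineticScheme and PhotophysicsModel field names.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import BindingEvent
from .hmm import Dwell
from .simulate import KineticScheme, PhotophysicsModel, StatePath
from .traces import TimeTrace, TraceSet

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_traces_hdf5", "read_traces_hdf5",
    "write_state_paths", "read_state_paths",
    "write_events_csv", "read_events_csv",
    "write_dwells_csv", "read_dwells_csv",
    "scheme_to_yaml", "scheme_from_yaml",
]


def write_traces_csv(path, traces: TraceSet) -> None:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time,
                    "DD": tr.DD,
                    "DA": tr.DA,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False)


def read_traces_csv(path, t_add: Optional[float] = None) -> TraceSet:
    df = pd.read_csv(path)
    traces = []
    for mol, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("frame")
        traces.append(
            TimeTrace(
                molecule_id=str(mol),
                time=g["time_s"].to_numpy(),
                DD=g["DD"].to_numpy(),
                DA=g["DA"].to_numpy(),
                t_add=t_add,
            )
        )
    dt = traces[0].frame_dt if traces and traces[0].n_frames > 1 else 0.04
    return TraceSet(traces=traces, frame_dt=dt, t_add=t_add)


def write_traces_hdf5(path, traces: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_dt"] = traces.frame_dt
        f.attrs["t_add"] = math.nan if traces.t_add is None else traces.t_add
        for tr in traces:
            g = f.create_group(tr.molecule_id)
            g.create_dataset("DD", data=tr.DD)
            g.create_dataset("DA", data=tr.DA)


def read_traces_hdf5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        frame_dt = float(f.attrs["frame_dt"])
        t_add = float(f.attrs["t_add"])
        t_add = None if math.isnan(t_add) else t_add
        traces = []
        for mol in sorted(f.keys()):
            DD = f[mol]["DD"][...]
            traces.append(
                TimeTrace(
                    molecule_id=mol,
                    time=np.arange(len(DD)) * frame_dt,
                    DD=DD,
                    DA=f[mol]["DA"][...],
                    t_add=t_add,
                )
            )
    return TraceSet(traces=traces, frame_dt=frame_dt, t_add=t_add)


def write_state_paths(path, paths: Sequence[StatePath], molecule_ids=None) -> None:
    ids = molecule_ids or [f"mol{i:04d}" for i in range(len(paths))]
    payload = {
        mid: {
            "segments": [[lab, t0, t1] for lab, t0, t1 in p.segments],
            "n_incorporated": p.n_incorporated,
            "incorporation_times": list(p.incorporation_times),
            "event_species": list(p.event_species),
        }
        for mid, p in zip(ids, paths)
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_state_paths(path) -> Dict[str, StatePath]:
    payload = json.loads(Path(path).read_text())
    return {
        mid: StatePath(
            segments=[tuple(seg) for seg in rec["segments"]],
            n_incorporated=rec["n_incorporated"],
            incorporation_times=rec["incorporation_times"],
            event_species=rec["event_species"],
        )
        for mid, rec in payload.items()
    }


_EVENT_COLS = [
    "molecule_id", "start_s", "end_s", "duration_s",
    "left_censored", "right_censored", "mean_E", "begins_closed", "species_guess",
]


def write_events_csv(path, events: Sequence[BindingEvent]) -> None:
    pd.DataFrame(
        [
            {
                "molecule_id": ev.molecule_id,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "duration_s": ev.duration,
                "left_censored": ev.left_censored,
                "right_censored": ev.right_censored,
                "mean_E": ev.mean_E,
                "begins_closed": ev.begins_closed,
                "species_guess": ev.species_guess,
                "frame_dt": ev.frame_dt,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
            }
            for ev in events
        ],
        columns=_EVENT_COLS + ["frame_dt", "start_frame", "end_frame"],
    ).to_csv(path, index=False)


def read_events_csv(path) -> List[BindingEvent]:
    df = pd.read_csv(path)
    return [
        BindingEvent(
            molecule_id=str(r.molecule_id),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            frame_dt=float(r.frame_dt),
            left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
            mean_E=float(r.mean_E),
            begins_closed=bool(r.begins_closed),
            species_guess=str(r.species_guess),
        )
        for r in df.itertuples()
    ]


def write_dwells_csv(path, dwells: Sequence[Dwell]) -> None:
    pd.DataFrame([dataclasses.asdict(d) for d in dwells]).to_csv(path, index=False)


def read_dwells_csv(path) -> List[Dwell]:
    df = pd.read_csv(path)
    return [
        Dwell(
            molecule_id=str(r.molecule_id),
            event_id=int(r.event_id),
            state_label=str(r.state_label),
            duration=float(r.duration),
            left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
            start_time=float(r.start_time),
        )
        for r in df.itertuples()
    ]


def scheme_to_yaml(path, scheme: KineticScheme, phys: PhotophysicsModel) -> None:
    payload = {
        "kinetics": dataclasses.asdict(scheme),
        "photophysics": dataclasses.asdict(phys),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def scheme_from_yaml(path):
    payload = yaml.safe_load(Path(path).read_text())
    scheme = KineticScheme(**payload.get("kinetics", {}))
    phys = PhotophysicsModel(**payload.get("photophysics", {}))
    scheme.validate()
    phys.validate()
    return scheme, phys
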