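"""Plain-text session files: TSV spike/event tables + JSON metadata.

A session on disk is three files in one directory:

* ``spikes.tsv`` — columns ``unit_id`` (int), ``time_s`` (float),
  sorted by unit then time;
* ``events.tsv`` — columns ``time_s``, ``event_type``
  (touch | microstim_pulse | phase_boundary), ``payload``;
* ``meta.json`` — seed, config hash, phase boundaries, unit positions
  and population labels, reference unit, and content hashes of the two
  TSV files.

Output is byte-stable for identical input, so hashes double as a
regression check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .session import Phase, SessionRecording

SPIKES_NAME = "spikes.tsv"
EVENTS_NAME = "events.tsv"
META_NAME = "meta.json"


@dataclass(frozen=True)
class SessionFileSet:
    spikes: Path
    events: Path
    meta: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_session(recording: SessionRecording, out_dir) -> SessionFileSet:
    """Write a session to ``out_dir``; deterministic byte-stable output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = SessionFileSet(
        spikes=out / SPIKES_NAME, events=out / EVENTS_NAME, meta=out / META_NAME
    )
    with open(paths.spikes, "w") as fh:
        fh.write("unit_id\ttime_s\n")
        for uid in recording.units:
            for t in recording.spike_times[uid]:
                fh.write(f"{uid}\t{t:.6f}\n")
    ev = recording.events.sort_values(
        ["time_s", "event_type"], kind="stable"
    ).reset_index(drop=True)
    with open(paths.events, "w") as fh:
        fh.write("time_s\tevent_type\tpayload\n")
        for _, row in ev.iterrows():
            fh.write(f"{row.time_s:.6f}\t{row.event_type}\t{row.payload}\n")
    meta = {
        "seed": recording.seed,
        "config_hash": recording.config_hash,
        "phases": [[p.label, p.start_s, p.end_s] for p in recording.phases],
        "units": recording.units,
        "unit_positions": (
            {str(k): list(v) for k, v in recording.unit_positions.items()}
            if recording.unit_positions
            else None
        ),
        "unit_populations": (
            {str(k): v for k, v in recording.unit_populations.items()}
            if recording.unit_populations
            else None
        ),
        "reference_unit": recording.reference_unit,
        "meta": _jsonable(recording.meta),
        "file_hashes": {
            SPIKES_NAME: _sha256(paths.spikes),
            EVENTS_NAME: _sha256(paths.events),
        },
    }
    paths.meta.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_session(path) -> SessionRecording:
    """Load and validate a session directory written by
    :func:`write_session`."""
    d = Path(path)
    paths = SessionFileSet(
        spikes=d / SPIKES_NAME, events=d / EVENTS_NAME, meta=d / META_NAME
    )
    for p in (paths.spikes, paths.events, paths.meta):
        if not p.exists():
            raise FileNotFoundError(f"missing session component: {p.name}")
    meta = json.loads(paths.meta.read_text())
    spikes = pd.read_csv(paths.spikes, sep="\t")
    if list(spikes.columns) != ["unit_id", "time_s"]:
        raise ValueError(f"{paths.spikes.name}: unexpected columns")
    if len(spikes) and spikes["time_s"].min() < 0:
        bad = int(np.argmax(spikes["time_s"].to_numpy() < 0)) + 2
        raise ValueError(f"{paths.spikes.name}:{bad}: negative spike time")
    events = pd.read_csv(
        paths.events, sep="\t", keep_default_na=False, dtype={"payload": str}
    )
    if list(events.columns) != ["time_s", "event_type", "payload"]:
        raise ValueError(f"{paths.events.name}: unexpected columns")
    spike_times = {int(u): np.empty(0) for u in meta.get("units", [])}
    for uid, grp in spikes.groupby("unit_id"):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"unit {uid}: spike times not sorted")
        spike_times[int(uid)] = t
    phases = [Phase(lbl, a, b) for lbl, a, b in meta["phases"]]
    return SessionRecording(
        spike_times=spike_times,
        events=events,
        phases=phases,
        unit_positions=(
            {int(k): tuple(v) for k, v in meta["unit_positions"].items()}
            if meta.get("unit_positions")
            else None
        ),
        unit_populations=(
            {int(k): v for k, v in meta["unit_populations"].items()}
            if meta.get("unit_populations")
            else None
        ),
        reference_unit=meta.get("reference_unit"),
        seed=meta.get("seed"),
        config_hash=meta.get("config_hash"),
        meta=meta.get("meta") or {},
    )
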