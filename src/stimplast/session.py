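"""Common in-memory representation of a recording session.

A session is a set of spike trains (one per unit), a log of stimulus
events, and a partition of the session into named phases
(``tactile_pre`` / ``conditioning`` / ``tactile_post``).  All times are
seconds from session start; unit positions, when known, are micrometres
within the cortical sheet.  The same container is produced by the
network simulator, the synthetic-session generator, and the file
reader, and consumed by every analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical phase labels, in temporal order
PHASE_LABELS = ("tactile_pre", "conditioning", "tactile_post")

#: recognised stimulus-event types
EVENT_TYPES = ("touch", "microstim_pulse", "phase_boundary")


@dataclass(frozen=True)
class Phase:
    """Half-open interval ``[start_s, end_s)`` of the session."""

    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.start_s) & (t < self.end_s)


@dataclass
class SessionRecording:
    """Spike trains + stimulus events + phase structure of one session.

    Parameters
    ----------
    spike_times
        Mapping unit id -> sorted array of spike times (seconds).
    events
        DataFrame with columns ``time_s`` (float), ``event_type``
        (one of :data:`EVENT_TYPES`), ``payload`` (str).
    phases
        Contiguous, non-overlapping :class:`Phase` intervals covering
        the session.
    unit_positions
        Optional mapping unit id -> (x, y) position in micrometres.
    unit_populations
        Optional mapping unit id -> population label.
    reference_unit
        Unit whose spikes triggered microstimulation, if any.
    seed, config_hash
        Provenance of the generating process.
    """

    spike_times: dict[int, np.ndarray]
    events: pd.DataFrame
    phases: list[Phase]
    unit_positions: dict[int, tuple[float, float]] | None = None
    unit_populations: dict[int, str] | None = None
    reference_unit: int | None = None
    seed: int | None = None
    config_hash: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for col in ("time_s", "event_type", "payload"):
            if col not in self.events.columns:
                raise ValueError(f"events table missing column {col!r}")
        bad = set(self.events["event_type"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        for uid, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
                raise ValueError(f"unit {uid}: spike times unsorted or negative")
            self.spike_times[uid] = t
        prev_end = None
        for ph in self.phases:
            if ph.end_s <= ph.start_s:
                raise ValueError(f"phase {ph.label}: empty or inverted interval")
            if prev_end is not None and not np.isclose(ph.start_s, prev_end):
                raise ValueError("phases not contiguous")
            prev_end = ph.end_s
        if len(self.events) and prev_end is not None:
            tmax = float(self.events["time_s"].max())
            if tmax > prev_end + 1e-9:
                raise ValueError("event beyond final phase boundary")

    # ------------------------------------------------------------------
    @property
    def units(self) -> list[int]:
        return sorted(self.spike_times)

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    @property
    def duration_s(self) -> float:
        return self.phases[-1].end_s if self.phases else 0.0

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(f"no phase labelled {label!r}")

    def spikes_in_phase(self, unit: int, label: str) -> np.ndarray:
        """Spike times of *unit* inside the phase, in session time."""
        ph = self.phase(label)
        t = self.spike_times[unit]
        return t[ph.contains(t)]

    def event_times(self, event_type: str, phase: str | None = None) -> np.ndarray:
        sel = self.events["event_type"] == event_type
        t = self.events.loc[sel, "time_s"].to_numpy(dtype=float)
        if phase is not None:
            t = t[self.phase(phase).contains(t)]
        return np.sort(t)

    def touch_times(self, phase: str) -> np.ndarray:
        return self.event_times("touch", phase)

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times.values()))


def make_phases(durations_s) -> list[Phase]:
    """Build the standard three-phase partition from a duration triple."""
    durations_s = list(durations_s)
    if len(durations_s) != 3 or any(d <= 0 for d in durations_s):
        raise ValueError("expected three positive phase durations")
    edges = np.concatenate([[0.0], np.cumsum(durations_s)])
    return [
        Phase(lbl, float(edges[i]), float(edges[i + 1]))
        for i, lbl in enumerate(PHASE_LABELS)
    ]
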