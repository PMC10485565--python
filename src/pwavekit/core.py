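"""Core domain containers and hypnogram/event algebra.

Conventions used throughout the package:

* Time is continuous seconds from session start; ``t0`` defaults to 0.
* All intervals (epochs, episodes, events) are half-open ``[onset, offset)``;
  an event exactly on an epoch boundary belongs to the later epoch.
* An event is assigned the vigilance state of the epoch containing its peak
  time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES = (WAKE, NREM, REM)

EVENT_COLUMNS = ("time", "onset", "offset", "amplitude", "duration", "state")

__all__ = [
    "WAKE", "NREM", "REM", "STATES", "EVENT_COLUMNS",
    "SignalTrace", "Hypnogram", "StateEpisode", "EventTable", "SpikeTrain",
    "episodes_from_hypnogram", "hypnogram_from_episodes",
    "event_rate_by_state", "inter_event_intervals",
]


@dataclass
class SignalTrace:
    """A uniformly sampled continuous channel.

    Sample ``i`` is at time ``t0 + i / rate``.
    """

    samples: np.ndarray
    rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    def index_at(self, t: float) -> int:
        """Nearest sample index to time t (clipped to valid range)."""
        return int(np.clip(round((t - self.t0) * self.rate), 0, len(self.samples) - 1))

    def slice(self, t_start: float, t_stop: float) -> "SignalTrace":
        """Half-open time slice [t_start, t_stop)."""
        i0 = max(int(np.ceil((t_start - self.t0) * self.rate - 1e-9)), 0)
        i1 = min(int(np.ceil((t_stop - self.t0) * self.rate - 1e-9)), len(self.samples))
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.rate)

    def with_samples(self, samples: np.ndarray, label: str | None = None,
                     rate: float | None = None) -> "SignalTrace":
        return SignalTrace(samples, rate if rate is not None else self.rate,
                           label if label is not None else self.label, self.t0)


@dataclass
class StateEpisode:
    """A maximal run of one vigilance state; half-open [onset, offset)."""

    state: str
    onset: float
    offset: float

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.offset > self.onset:
            raise ValueError("episode offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.onset) & (t < self.offset)


@dataclass
class Hypnogram:
    """Fixed-length vigilance-state epochs (default 4 s) tiling a session."""

    states: np.ndarray
    epoch_len: float = 4.0
    t0: float = 0.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="U8")
        if not self.epoch_len > 0:
            raise ValueError("epoch_len must be > 0")
        if len(self.states) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = ~np.isin(self.states, STATES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"unknown state label {self.states[i]!r} at epoch {i}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration(self) -> float:
        return len(self.states) * self.epoch_len

    @property
    def span(self) -> tuple[float, float]:
        return self.t0, self.t0 + self.duration

    def epoch_index(self, t) -> np.ndarray:
        """Epoch index containing each time (half-open epochs); errors if outside."""
        t = np.asarray(t, dtype=float)
        idx = np.floor((t - self.t0) / self.epoch_len).astype(int)
        out = (idx < 0) | (idx >= len(self.states))
        if out.any():
            bad = np.atleast_1d(t)[np.atleast_1d(out)]
            raise ValueError(f"time(s) outside hypnogram span: {bad[:5]}")
        return idx

    def state_at(self, t) -> np.ndarray:
        return self.states[self.epoch_index(t)]

    def state_duration(self, state: str) -> float:
        return float(np.sum(self.states == state)) * self.epoch_len

    def episodes(self) -> list[StateEpisode]:
        return episodes_from_hypnogram(self)


def episodes_from_hypnogram(h: Hypnogram) -> list[StateEpisode]:
    """Maximal runs of identical state, in order; they tile the hypnogram span."""
    change = np.flatnonzero(h.states[1:] != h.states[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(h.states)]])
    return [
        StateEpisode(str(h.states[i]), h.t0 + i * h.epoch_len, h.t0 + j * h.epoch_len)
        for i, j in zip(starts, stops)
    ]


def hypnogram_from_episodes(episodes: list[StateEpisode], epoch_len: float = 4.0) -> Hypnogram:
    """Re-encode contiguous episodes as a hypnogram (inverse of episode derivation)."""
    if not episodes:
        raise ValueError("no episodes")
    labels = []
    for ep in episodes:
        n = (ep.offset - ep.onset) / epoch_len
        if abs(n - round(n)) > 1e-9:
            raise ValueError("episode bounds are not multiples of epoch_len")
        labels.extend([ep.state] * int(round(n)))
    return Hypnogram(np.array(labels), epoch_len=epoch_len, t0=episodes[0].onset)


class EventTable:
    """Detected events: peak time, onset/offset bounds, amplitude, state.

    Thin wrapper around a pandas DataFrame with validated invariants
    (strictly increasing times, onset <= time <= offset, duration =
    offset - onset) plus a ``meta`` dict recording detector provenance.
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None):
        df = df.reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        df = df.loc[:, list(EVENT_COLUMNS)]
        if len(df):
            t = df["time"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            on = df["onset"].to_numpy(float)
            off = df["offset"].to_numpy(float)
            if np.any(on > t) or np.any(t > off):
                raise ValueError("events must satisfy onset <= time <= offset")
            if np.any(np.abs((off - on) - df["duration"].to_numpy(float)) > 1e-9):
                raise ValueError("duration must equal offset - onset")
            bad = ~df["state"].isin(STATES)
            if bad.any():
                raise ValueError(f"unknown state label(s): {df.loc[bad, 'state'].unique()}")
        self.df = df
        self.meta = dict(meta or {})

    @classmethod
    def from_arrays(cls, times, onsets=None, offsets=None, amplitudes=None,
                    states=None, meta=None) -> "EventTable":
        times = np.asarray(times, dtype=float)
        n = len(times)
        onsets = times if onsets is None else np.asarray(onsets, dtype=float)
        offsets = times if offsets is None else np.asarray(offsets, dtype=float)
        amplitudes = np.zeros(n) if amplitudes is None else np.asarray(amplitudes, dtype=float)
        if states is None:
            states = np.full(n, WAKE)
        elif isinstance(states, str):
            states = np.full(n, states)
        df = pd.DataFrame({
            "time": times, "onset": onsets, "offset": offsets,
            "amplitude": amplitudes, "duration": offsets - onsets,
            "state": np.asarray(states),
        })
        return cls(df, meta)

    @classmethod
    def empty(cls, meta=None) -> "EventTable":
        return cls(pd.DataFrame({c: [] for c in EVENT_COLUMNS}), meta)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(float)

    @property
    def durations(self) -> np.ndarray:
        return self.df["duration"].to_numpy(float)

    @property
    def states(self) -> np.ndarray:
        return self.df["state"].to_numpy()

    def select_state(self, *states: str) -> "EventTable":
        return EventTable(self.df[self.df["state"].isin(states)], self.meta)

    def select(self, mask) -> "EventTable":
        return EventTable(self.df[np.asarray(mask, dtype=bool)], self.meta)


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit."""

    unit_id: str
    times: np.ndarray
    region: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and (np.any(np.diff(self.times) < 0) or self.times[0] < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be sorted and non-negative")

    def __len__(self) -> int:
        return len(self.times)


def event_rate_by_state(events: EventTable, h: Hypnogram,
                        states: tuple[str, ...] = STATES) -> dict[str, float]:
    """Event rate (Hz) per vigilance state.

    rate(s) = (# events whose peak time falls in state-s epochs) / total
    time spent in s.  A state with zero total duration maps to NaN
    (undefined), never 0.  Events outside the hypnogram span raise.
    """
    t = events.times
    if len(t):
        lo, hi = h.span
        out = (t < lo) | (t >= hi)
        if out.any():
            raise ValueError(f"event(s) outside hypnogram span: {t[out][:5]}")
        ev_states = h.state_at(t)
    else:
        ev_states = np.array([], dtype="U8")
    rates: dict[str, float] = {}
    for s in states:
        dur = h.state_duration(s)
        rates[s] = float(np.sum(ev_states == s)) / dur if dur > 0 else float("nan")
    return rates


def inter_event_intervals(events: EventTable,
                          episodes: list[StateEpisode] | Hypnogram | None = None
                          ) -> tuple[np.ndarray, float]:
    """First differences of event times, restricted to within-episode pairs.

    If ``episodes`` (or a hypnogram to derive them from) is given, only
    consecutive event pairs falling in the same state episode contribute.
    Returns (intervals, median); the median is NaN when no intervals exist.
    """
    t = events.times
    if len(t) < 2:
        return np.array([]), float("nan")
    keep = np.ones(len(t) - 1, dtype=bool)
    if episodes is not None:
        if isinstance(episodes, Hypnogram):
            episodes = episodes.episodes()
        ep_id = np.full(len(t), -1)
        for k, ep in enumerate(episodes):
            ep_id[ep.contains(t)] = k
        keep = (ep_id[:-1] == ep_id[1:]) & (ep_id[:-1] >= 0)
    iv = np.diff(t)[keep]
    med = float(np.median(iv)) if len(iv) else float("nan")
    return iv, med
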