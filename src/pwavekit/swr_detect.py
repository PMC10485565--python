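"""Hippocampal sharp wave-ripple (SWR) detection.

Dual-threshold envelope procedure: band-pass 80-250 Hz (third-order
Butterworth, zero phase), centered 20-ms sliding RMS envelope at sample
stride, then two thresholds from the envelope's own mean/SD over the
whole recording - mean + 5 SD seeds candidates and mean + 2 SD defines
their onset/offset.  Candidates with overlapping bounds are merged (peak
at the envelope maximum of the merged span) and events shorter than
20 ms or longer than 200 ms are discarded last.

For multichannel probes the CA1 pyramidal-layer channel is identified as
the one maximizing the NREM/REM SWR-rate ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dsp import butter_bandpass, sliding_rms
from .core import EventTable, Hypnogram, NREM, REM, SignalTrace
from .core import event_rate_by_state

__all__ = [
    "SWRDetectorParams", "ripple_envelope", "detect_swrs",
    "detect_from_envelope", "select_channel", "coupled_swr_partition",
]


@dataclass
class SWRDetectorParams:
    band: tuple = (80.0, 250.0)
    filter_order: int = 3
    env_window: float = 0.020
    peak_k: float = 5.0
    bound_k: float = 2.0
    min_dur: float = 0.020
    max_dur: float = 0.200
    #: how far (s) the boundary-threshold search may extend from a seed
    max_extent: float = 0.500

    def __post_init__(self):
        if not self.min_dur < self.max_dur:
            raise ValueError("min_dur must be < max_dur")
        if not self.peak_k > self.bound_k > 0:
            raise ValueError("need peak_k > bound_k > 0")


def ripple_envelope(lfp: SignalTrace, params: SWRDetectorParams | None = None) -> SignalTrace:
    """Zero-phase ripple-band filter + centered sliding RMS, at input rate."""
    params = params or SWRDetectorParams()
    lo, hi = params.band
    if lfp.rate <= 2 * hi:
        raise ValueError(f"sampling rate {lfp.rate} Hz too low for band up to {hi} Hz")
    filt = butter_bandpass(lfp.samples, lfp.rate, lo, hi, params.filter_order)
    env = sliding_rms(filt, lfp.rate, params.env_window)
    return SignalTrace(env, lfp.rate, f"{lfp.label}[ripple-env]", lfp.t0)


def detect_from_envelope(env: np.ndarray, rate: float,
                         params: SWRDetectorParams | None = None,
                         t0: float = 0.0,
                         mean: float | None = None,
                         sd: float | None = None) -> pd.DataFrame:
    """Dual-threshold event extraction from a precomputed envelope.

    Exposed separately so the interval logic can be validated directly
    against brute-force scans of arbitrary envelopes.  Returns a frame
    with columns onset, offset, time (peak), amplitude, duration.
    """
    params = params or SWRDetectorParams()
    env = np.asarray(env, dtype=float)
    mean = float(env.mean()) if mean is None else mean
    sd = float(env.std()) if sd is None else sd
    peak_thr = mean + params.peak_k * sd
    bound_thr = mean + params.bound_k * sd
    max_ext = int(round(params.max_extent * rate))

    above_peak = env > peak_thr
    if not above_peak.any():
        return pd.DataFrame(columns=["onset", "offset", "time", "amplitude", "duration"])
    d = np.diff(above_peak.astype(int))
    seed_starts = list(np.flatnonzero(d == 1) + 1)
    seed_stops = list(np.flatnonzero(d == -1) + 1)
    if above_peak[0]:
        seed_starts.insert(0, 0)
    if above_peak[-1]:
        seed_stops.append(len(env))

    below = env <= bound_thr
    cands = []
    for a, b in zip(seed_starts, seed_stops):
        lo = a
        limit = max(a - max_ext, 0)
        seg = below[limit:a][::-1]
        hit = np.flatnonzero(seg)
        lo = a - (int(hit[0]) + 1) + 1 if len(hit) else limit
        hi = b
        limit = min(b + max_ext, len(env))
        seg = below[b:limit]
        hit = np.flatnonzero(seg)
        hi = b + int(hit[0]) if len(hit) else limit
        cands.append([lo, hi])

    merged: list[list[int]] = []
    for lo, hi in cands:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    rows = []
    for lo, hi in merged:
        dur = (hi - lo) / rate
        if dur < params.min_dur or dur > params.max_dur:
            continue
        j = lo + int(np.argmax(env[lo:hi]))
        rows.append((t0 + lo / rate, t0 + hi / rate, t0 + j / rate,
                     float(env[j]), dur))
    return pd.DataFrame(rows, columns=["onset", "offset", "time", "amplitude", "duration"])


def detect_swrs(lfp: SignalTrace, h: Hypnogram,
                params: SWRDetectorParams | None = None,
                stats_state: str | None = None) -> EventTable:
    """Detect SWRs on one LFP channel and label each with its sleep state.

    Envelope mean/SD are taken over the whole recording by default;
    ``stats_state`` restricts them to epochs of one state instead.
    """
    params = params or SWRDetectorParams()
    env_tr = ripple_envelope(lfp, params)
    env = env_tr.samples
    if stats_state is not None:
        mask = h.state_at(np.clip(env_tr.times, *np.nextafter(h.span, h.span[0]))) == stats_state
        if not mask.any():
            raise ValueError(f"no {stats_state} samples for envelope statistics")
        mean, sd = float(env[mask].mean()), float(env[mask].std())
    else:
        mean, sd = float(env.mean()), float(env.std())
    df = detect_from_envelope(env, lfp.rate, params, t0=lfp.t0, mean=mean, sd=sd)
    meta = {
        "detector": "swr",
        "band_hz": params.band,
        "filter": f"butterworth order {params.filter_order}, zero phase",
        "peak_threshold": mean + params.peak_k * sd,
        "bound_threshold": mean + params.bound_k * sd,
        "envelope_mean": mean, "envelope_sd": sd,
        "stats_state": stats_state or "all",
        "channel": lfp.label,
    }
    if not len(df):
        return EventTable.empty(meta)
    lo_t, hi_t = h.span
    df = df[(df["time"] >= lo_t) & (df["time"] < hi_t)]
    if not len(df):
        return EventTable.empty(meta)
    states = h.state_at(df["time"].to_numpy())
    return EventTable.from_arrays(df["time"].to_numpy(), df["onset"].to_numpy(),
                                  df["offset"].to_numpy(), df["amplitude"].to_numpy(),
                                  states, meta)


def select_channel(lfps: dict[str, SignalTrace], h: Hypnogram,
                   params: SWRDetectorParams | None = None
                   ) -> tuple[str, pd.DataFrame]:
    """Pick the putative CA1 pyramidal-layer channel.

    Runs the detector per channel and ranks channels by the ratio of SWR
    rates NREM/REM; zero REM rate with nonzero NREM rate counts as
    infinitely preferred, channels with no SWRs in either state are
    ineligible.  Ties break toward the higher absolute NREM rate.
    Returns (chosen label, per-channel report frame).
    """
    if not lfps:
        raise ValueError("no channels supplied")
    rows = []
    for label, tr in lfps.items():
        events = detect_swrs(tr, h, params)
        rates = event_rate_by_state(events, h)
        r_n = rates.get(NREM, float("nan"))
        r_r = rates.get(REM, float("nan"))
        if np.isnan(r_n) or (r_n == 0 and (np.isnan(r_r) or r_r == 0)):
            ratio = float("nan")
        elif np.isnan(r_r) or r_r == 0:
            ratio = float("inf")
        else:
            ratio = r_n / r_r
        rows.append((label, len(events), r_n, r_r, ratio))
    report = pd.DataFrame(rows, columns=["channel", "n_swr", "rate_nrem", "rate_rem", "ratio"])
    eligible = report.dropna(subset=["ratio"])
    if not len(eligible):
        raise ValueError("no eligible channel: no SWRs detected on any channel")
    best = eligible.sort_values(["ratio", "rate_nrem"], ascending=False).iloc[0]
    return str(best["channel"]), report


def coupled_swr_partition(swrs: EventTable, pwaves: EventTable,
                          window: float = 0.030) -> tuple[EventTable, EventTable]:
    """Split SWRs by whether a P-wave falls within ``window`` of the SWR
    peak (peak-to-peak distance, boundary inclusive).  The partition is
    exhaustive and disjoint; sweep ``window`` to probe robustness."""
    if window <= 0:
        raise ValueError("window must be > 0")
    ts = swrs.times
    tp = pwaves.times
    if len(ts) == 0 or len(tp) == 0:
        return swrs.select(np.zeros(len(ts), dtype=bool)), swrs.select(np.ones(len(ts), dtype=bool))
    idx = np.searchsorted(tp, ts)
    left = np.abs(ts - tp[np.clip(idx - 1, 0, len(tp) - 1)])
    right = np.abs(tp[np.clip(idx, 0, len(tp) - 1)] - ts)
    nearest = np.minimum(left, right)
    coupled = nearest <= window
    return swrs.select(coupled), swrs.select(~coupled)
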