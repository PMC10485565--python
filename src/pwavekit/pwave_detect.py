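"""P-wave detection from a bipolar pontine derivation.

Pipeline: subtract the two pontine channels (removes volume-conducted
activity), band-pass 5-30 Hz (zero phase), compute a 10-ms windowed RMS
envelope, and threshold it at mean + 5 SD of the envelope statistics
taken from the longest NREM episode (the cleanest available noise
segment).  Candidate periods closer than a merge gap are fused, any
candidate with a concurrent EMG excursion (mean + 3 SD of the EMG RMS
from the same NREM segment) is vetoed as a movement artifact, and the
event time is the most negative filtered sample in the candidate - the
P-wave trough.

Because all thresholds are derived from the data, detection is invariant
to rescaling the inputs by a common positive factor.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._dsp import butter_bandpass, window_rms
from .core import EventTable, Hypnogram, NREM, SignalTrace, StateEpisode

__all__ = [
    "PWaveDetectorParams", "NoiseEstimate",
    "differential_signal", "bandpass", "rms_envelope",
    "noise_threshold", "detect_pwaves", "run_pwave_detection",
    "bilateral_xcorr", "waveform_gallery", "waveform_similarity", "pca_project",
]


@dataclass
class PWaveDetectorParams:
    band: tuple = (5.0, 30.0)
    rms_window: float = 0.010
    signal_k: float = 5.0
    emg_k: float = 3.0
    emg_window: float = 0.010
    merge_gap: float = 0.050
    emg_veto_halfwidth: float = 0.050
    filter_order: int = 3
    #: 'envelope' thresholds the windowed RMS of the filtered signal;
    #: 'amplitude' thresholds the instantaneous |filtered| samples.
    threshold_mode: str = "envelope"

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if self.rms_window <= 0 or self.emg_window <= 0:
            raise ValueError("RMS windows must be > 0")
        if self.signal_k <= 0 or self.emg_k <= 0:
            raise ValueError("threshold multipliers must be > 0")
        if self.threshold_mode not in ("envelope", "amplitude"):
            raise ValueError("threshold_mode must be 'envelope' or 'amplitude'")


@dataclass
class NoiseEstimate:
    """Envelope statistics from the longest NREM episode."""

    episode: StateEpisode
    rms_mean: float
    rms_sd: float
    k: float

    @property
    def threshold(self) -> float:
        return self.rms_mean + self.k * self.rms_sd


def differential_signal(ch_a: SignalTrace, ch_b: SignalTrace) -> SignalTrace:
    """Samplewise a - b; cancels components common to both electrodes."""
    if ch_a.rate != ch_b.rate:
        raise ValueError(f"rate mismatch: {ch_a.rate} vs {ch_b.rate}")
    if len(ch_a) != len(ch_b):
        raise ValueError(f"length mismatch: {len(ch_a)} vs {len(ch_b)}")
    return SignalTrace(ch_a.samples - ch_b.samples, ch_a.rate,
                       f"{ch_a.label}-{ch_b.label}", ch_a.t0)


def bandpass(trace: SignalTrace, low: float, high: float, order: int = 3) -> SignalTrace:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    return trace.with_samples(butter_bandpass(trace.samples, trace.rate, low, high, order),
                              label=f"{trace.label}[{low}-{high}Hz]")


def rms_envelope(trace: SignalTrace, window: float) -> SignalTrace:
    """Non-overlapping windowed RMS; output rate = 1/window."""
    vals, out_rate = window_rms(trace.samples, trace.rate, window)
    return SignalTrace(vals, out_rate, f"{trace.label}[rms]", trace.t0)


def _longest_nrem(h: Hypnogram) -> StateEpisode:
    nrem = [ep for ep in h.episodes() if ep.state == NREM]
    if not nrem:
        raise ValueError("no NREM episode in hypnogram; supply a manual threshold")
    return max(nrem, key=lambda ep: ep.duration)


def noise_threshold(filtered: SignalTrace, h: Hypnogram,
                    params: PWaveDetectorParams | None = None,
                    k: float | None = None,
                    window: float | None = None) -> NoiseEstimate:
    """Envelope mean/SD over the longest NREM episode -> mean + k*SD."""
    params = params or PWaveDetectorParams()
    k = params.signal_k if k is None else k
    window = params.rms_window if window is None else window
    ep = _longest_nrem(h)
    seg = filtered.slice(ep.onset, ep.offset)
    env, _ = window_rms(seg.samples, seg.rate, window)
    return NoiseEstimate(ep, float(env.mean()), float(env.std()), k)


def _runs_above(x: np.ndarray, thr: float) -> list[tuple[int, int]]:
    above = x > thr
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(x))
    return list(zip(starts, stops))


def detect_pwaves(filtered: SignalTrace, emg: SignalTrace, h: Hypnogram,
                  params: PWaveDetectorParams | None = None) -> EventTable:
    """Detect P-waves on a band-passed differential pontine trace.

    Returns an EventTable whose ``time`` is the filtered-signal trough
    within each suprathreshold candidate, with thresholds and veto counts
    recorded in ``meta``.  Wake-state events are labelled WAKE and can be
    excluded via ``EventTable.select_state``.
    """
    params = params or PWaveDetectorParams()
    noise = noise_threshold(filtered, h, params)
    thr = noise.threshold

    # EMG veto statistics from the same longest-NREM segment.
    emg_seg = emg.slice(noise.episode.onset, noise.episode.offset)
    emg_ref, _ = window_rms(emg_seg.samples, emg_seg.rate, params.emg_window)
    emg_thr = float(emg_ref.mean() + params.emg_k * emg_ref.std())
    emg_env, emg_env_rate = window_rms(emg.samples, emg.rate, params.emg_window)

    if params.threshold_mode == "envelope":
        env, env_rate = window_rms(filtered.samples, filtered.rate, params.rms_window)
        runs = _runs_above(env, thr)
        cand = [(filtered.t0 + a / env_rate, filtered.t0 + b / env_rate) for a, b in runs]
    else:
        runs = _runs_above(np.abs(filtered.samples), thr)
        cand = [(filtered.t0 + a / filtered.rate, filtered.t0 + b / filtered.rate)
                for a, b in runs]

    # Merge candidates separated by less than merge_gap.
    merged: list[list[float]] = []
    for on, off in cand:
        if merged and on - merged[-1][1] < params.merge_gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])

    n_vetoed = 0
    times, onsets, offsets, amps = [], [], [], []
    lo_t, hi_t = h.span
    for on, off in merged:
        # EMG veto: any suprathreshold EMG RMS within +/- halfwidth.
        i0 = max(int(np.floor((on - params.emg_veto_halfwidth - emg.t0) * emg_env_rate)), 0)
        i1 = min(int(np.ceil((off + params.emg_veto_halfwidth - emg.t0) * emg_env_rate)) + 1,
                 len(emg_env))
        if i1 > i0 and np.any(emg_env[i0:i1] > emg_thr):
            n_vetoed += 1
            continue
        seg = filtered.slice(on, off)
        if len(seg.samples) == 0:
            continue
        j = int(np.argmin(seg.samples))
        t = seg.t0 + j / seg.rate
        if not (lo_t <= t < hi_t):
            continue
        times.append(t)
        onsets.append(on)
        offsets.append(off)
        amps.append(float(seg.samples[j]))

    meta = {
        "detector": "pwave",
        "band_hz": params.band,
        "filter": f"butterworth order {params.filter_order}, zero phase",
        "threshold_mode": params.threshold_mode,
        "signal_threshold": thr,
        "signal_rms_mean": noise.rms_mean,
        "signal_rms_sd": noise.rms_sd,
        "emg_threshold": emg_thr,
        "noise_episode": (noise.episode.onset, noise.episode.offset),
        "n_vetoed": n_vetoed,
        "merge_gap_s": params.merge_gap,
    }
    if not times:
        return EventTable.empty(meta)
    states = h.state_at(np.asarray(times))
    return EventTable.from_arrays(times, onsets, offsets, amps, states, meta)


def run_pwave_detection(ch_a: SignalTrace, ch_b: SignalTrace, emg: SignalTrace,
                        h: Hypnogram,
                        params: PWaveDetectorParams | None = None) -> EventTable:
    """Convenience wrapper: differential -> band-pass -> detect."""
    params = params or PWaveDetectorParams()
    diff = differential_signal(ch_a, ch_b)
    filt = bandpass(diff, *params.band, order=params.filter_order)
    return detect_pwaves(filt, emg, h, params)


def bilateral_xcorr(left: EventTable, right: EventTable,
                    bin_width: float = 0.010, max_lag: float = 0.5
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram of right-event lags relative to each left event.

    Returns (lag bin centers, counts) on a symmetric lag axis with the
    central bin centered on zero lag.
    """
    if bin_width <= 0:
        raise ValueError("bin must be > 0")
    if max_lag < bin_width:
        raise ValueError("max_lag must be >= bin")
    half_bins = int(np.floor(max_lag / bin_width))
    edges = (np.arange(-half_bins, half_bins + 2) - 0.5) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0
    tl, tr = left.times, right.times
    if len(tl) == 0 or len(tr) == 0:
        return centers, np.zeros(len(centers), dtype=int)
    lags = []
    for t in tl:
        lo = np.searchsorted(tr, t + edges[0])
        hi = np.searchsorted(tr, t + edges[-1])
        lags.append(tr[lo:hi] - t)
    counts, _ = np.histogram(np.concatenate(lags) if lags else [], bins=edges)
    return centers, counts


def waveform_gallery(trace: SignalTrace, events: EventTable,
                     halfwidth: float = 0.050):
    """Event-aligned waveform matrix with mean and SD traces.

    Windows clipped by the trace edges are skipped; the number skipped is
    returned so callers can warn.  Returns (matrix, lags, mean, sd,
    n_skipped); matrix is empty (0 rows) when there are no usable events.
    """
    n_half = int(round(halfwidth * trace.rate))
    lags = np.arange(-n_half, n_half + 1) / trace.rate
    rows = []
    n_skipped = 0
    for t in events.times:
        i = int(round((t - trace.t0) * trace.rate))
        if i - n_half < 0 or i + n_half + 1 > len(trace.samples):
            n_skipped += 1
            continue
        rows.append(trace.samples[i - n_half:i + n_half + 1])
    if rows:
        mat = np.vstack(rows)
        return mat, lags, mat.mean(axis=0), mat.std(axis=0), n_skipped
    empty = np.empty((0, len(lags)))
    return empty, lags, None, None, n_skipped


def waveform_similarity(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Pearson r of two mean waveforms; NaN if either has zero variance."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("waveform lengths differ")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pca_project(*galleries: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Project pooled event waveforms onto their first two principal
    components (components ordered by explained variance).

    Returns (pooled scores, per-gallery score arrays in input order).
    """
    from sklearn.decomposition import PCA

    pooled = np.vstack([g for g in galleries if len(g)])
    if len(pooled) < 2:
        raise ValueError("need at least two waveforms for PCA")
    scores = PCA(n_components=2).fit_transform(pooled)
    out, k = [], 0
    for g in galleries:
        out.append(scores[k:k + len(g)])
        k += len(g)
    return scores, out
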