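"""Fiber-photometry processing: pulse-wise downsampling, exponential
de-bleaching, low-pass filtering, isosbestic motion correction, and
event-triggered normalized responses.

The dual-excitation scheme alternates 470 nm (activity-dependent) and
405 nm (isosbestic, activity-independent) LED pulses at an effective
40 Hz.  Motion and residual bleaching appear in both channels; calcium
transients only in the 470 nm channel, so regressing the 405 signal out
of the 470 signal isolates activity.

Sign convention: the corrected trace is ``470 - (slope*405 + intercept)``
so that calcium transients are positive deflections.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._dsp import filtfilt_fir, fir_lowpass
from .core import SignalTrace

__all__ = [
    "PhotometrySession", "ProcessedPhotometry",
    "pulse_downsample", "debleach", "lowpass", "isosbestic_correct",
    "process_session", "event_triggered_photometry",
]


@dataclass
class PhotometrySession:
    """Per-pulse 470/405 nm values on a common 40 Hz time base."""

    pulse_times: np.ndarray
    raw_470: np.ndarray
    raw_405: np.ndarray
    rate: float = 40.0

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.raw_470 = np.asarray(self.raw_470, dtype=float)
        self.raw_405 = np.asarray(self.raw_405, dtype=float)
        if not (len(self.pulse_times) == len(self.raw_470) == len(self.raw_405)):
            raise ValueError("pulse_times, raw_470 and raw_405 must have equal lengths")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


@dataclass
class ProcessedPhotometry:
    dff: SignalTrace
    bleach_470: dict
    bleach_405: dict
    slope: float
    intercept: float
    flags: list = field(default_factory=list)


def pulse_downsample(pulse_windows) -> np.ndarray:
    """Median fluorescence per LED pulse window -> one sample per pulse.

    ``pulse_windows`` is a sequence of per-pulse raw sample arrays (or a
    2-D array, pulses x samples).  The median is robust to single-sample
    glitches within a pulse.
    """
    out = np.empty(len(pulse_windows))
    for i, w in enumerate(pulse_windows):
        w = np.asarray(w, dtype=float)
        if w.size == 0:
            raise ValueError(f"empty pulse window at index {i}")
        out[i] = np.median(w)
    return out


def debleach(trace: np.ndarray, rate: float = 40.0) -> tuple[np.ndarray, dict]:
    """Remove photobleaching by subtracting a fitted single exponential.

    Fits ``a*exp(-t/tau) + c`` by least squares; if the fit does not
    converge or the exponential is unidentifiable (near-constant trace),
    falls back to a linear detrend and flags it.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 10 * rate:
        raise ValueError("trace shorter than 10 s; bleaching fit is unreliable")
    t = np.arange(len(x)) / rate
    span = x.max() - x.min()
    params = {"amplitude": np.nan, "tau": np.nan, "offset": np.nan,
              "fallback_linear": False, "unidentifiable": False}
    if span < 1e-12 or span < 1e-6 * max(abs(x.mean()), 1e-12):
        params.update(offset=float(x.mean()), unidentifiable=True)
        return x - x.mean(), params

    a0 = x[:max(len(x) // 20, 1)].mean() - x[-max(len(x) // 20, 1):].mean()
    c0 = x[-max(len(x) // 20, 1):].mean()
    tau0 = t[-1] / 3.0
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t, x, p0=[a0 if abs(a0) > 1e-12 else span, tau0, c0],
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000)
        a, tau, c = popt
        fit = a * np.exp(-t / tau) + c
        params.update(amplitude=float(a), tau=float(tau), offset=float(c))
        return x - fit, params
    except RuntimeError:
        coef = np.polyfit(t, x, 1)
        params["fallback_linear"] = True
        return x - np.polyval(coef, t), params


def lowpass(trace: np.ndarray, rate: float = 40.0, cutoff: float = 4.0) -> np.ndarray:
    """Zero-phase FIR low-pass (< cutoff Hz)."""
    b = fir_lowpass(rate, cutoff)
    return filtfilt_fir(b, np.asarray(trace, dtype=float))


def isosbestic_correct(sig470: np.ndarray, sig405: np.ndarray
                       ) -> tuple[np.ndarray, dict]:
    """Regress the isosbestic channel out of the activity channel.

    Ordinary least squares of 470 on 405 gives the scaling of the shared
    (motion) component; the corrected trace is the 470 signal minus the
    scaled 405 signal.  If the 405 channel has no variance the output is
    the mean-centered 470 signal, flagged in the returned params.
    """
    x470 = np.asarray(sig470, dtype=float)
    x405 = np.asarray(sig405, dtype=float)
    if len(x470) != len(x405):
        raise ValueError("channel lengths differ")
    v = x405.var()
    if v < 1e-30:
        return x470 - x470.mean(), {"slope": 0.0, "intercept": float(x470.mean()),
                                    "degenerate_405": True}
    slope = float(np.cov(x405, x470, bias=True)[0, 1] / v)
    intercept = float(x470.mean() - slope * x405.mean())
    return x470 - (slope * x405 + intercept), {"slope": slope, "intercept": intercept,
                                               "degenerate_405": False}


def process_session(session: PhotometrySession) -> ProcessedPhotometry:
    """Full pipeline: de-bleach each channel, low-pass (<4 Hz), regress the
    isosbestic channel out, return the corrected activity trace."""
    flags = []
    c470, p470 = debleach(session.raw_470, session.rate)
    c405, p405 = debleach(session.raw_405, session.rate)
    for name, p in (("470", p470), ("405", p405)):
        if p["fallback_linear"]:
            flags.append(f"bleach fit fell back to linear detrend on {name}")
        if p["unidentifiable"]:
            flags.append(f"bleach time constant unidentifiable on {name}")
    f470 = lowpass(c470, session.rate)
    f405 = lowpass(c405, session.rate)
    dff, reg = isosbestic_correct(f470, f405)
    if reg["degenerate_405"]:
        flags.append("isosbestic channel has zero variance; returned centered 470")
    t0 = float(session.pulse_times[0]) if len(session.pulse_times) else 0.0
    return ProcessedPhotometry(
        dff=SignalTrace(dff, session.rate, "dff", t0=t0),
        bleach_470=p470, bleach_405=p405,
        slope=reg["slope"], intercept=reg["intercept"], flags=flags)


def event_triggered_photometry(dff: SignalTrace, event_times,
                               window: tuple[float, float] = (-10.0, 10.0),
                               normalize: bool = True):
    """Event-aligned snippets of the corrected trace.

    Each snippet is z-scored over the analysis window (when ``normalize``),
    matching the convention that a |z| of 1.96 bounds pointwise p = 0.05.
    Returns (matrix events x samples, lags, mean trace, PC1 sort order).
    """
    event_times = np.asarray(event_times, dtype=float)
    pre, post = window
    n_pre = int(round(-pre * dff.rate))
    n_post = int(round(post * dff.rate))
    lags = np.arange(-n_pre, n_post + 1) / dff.rate
    rows = []
    for t in event_times:
        i = int(round((t - dff.t0) * dff.rate))
        if i - n_pre < 0 or i + n_post + 1 > len(dff.samples):
            continue
        snip = dff.samples[i - n_pre:i + n_post + 1].copy()
        if normalize:
            sd = snip.std()
            snip = (snip - snip.mean()) / sd if sd > 0 else snip - snip.mean()
        rows.append(snip)
    if not rows:
        raise ValueError("no event window fits inside the trace")
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    if len(mat) >= 2:
        centered = mat - mat.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[0]
        order = np.argsort(scores)
    else:
        order = np.arange(len(mat))
    return mat, lags, mean, order
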