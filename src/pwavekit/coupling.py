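"""Event-centred coupling statistics.

Everything downstream of the detectors lives here: theta phase of events
(Hilbert phase of a Kaiser-FIR band-passed differential LFP), circular
statistics (resultant vector length, Rayleigh test), band-power
cross-correlations with event times, asymmetry/modulation indices,
peri-event time histograms of spiking, within-episode event-rate
profiles, the spectral dependency ratio (SDR) for directional coupling,
and a random-intercept mixed model linking episode duration to event
rate.

Phase convention: 0 rad at band-filtered signal peaks, +/-pi at troughs,
increasing with time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from ._dsp import butter_bandpass, filtfilt_fir, kaiser_fir_bandpass, sliding_rms
from .core import EventTable, SignalTrace, SpikeTrain, StateEpisode

__all__ = [
    "ThetaFilterSpec", "PhaseLockResult", "IndexResult", "LMEResult", "PethResult",
    "theta_phase", "phase_locking", "rayleigh_test",
    "band_power_trace", "event_power_xcorr",
    "asymmetry_index", "modulation_index", "theta_power_windows",
    "peth", "profile_similarity", "episode_quartile_profile",
    "sdr", "episode_duration_model",
]


# ------------------------------------------------------------ theta phase

@dataclass
class ThetaFilterSpec:
    band: tuple = (4.0, 10.0)
    transition: float = 1.0
    pass_ripple_db: float = 0.01
    stop_atten_db: float = 50.0


def theta_phase(lfp_a: SignalTrace, lfp_b: SignalTrace | None = None,
                spec: ThetaFilterSpec | None = None) -> SignalTrace:
    """Instantaneous theta phase of the (differential) LFP.

    Subtracts the second channel when given (volume-conduction removal),
    applies the Kaiser FIR band-pass forward-backward (zero net phase),
    and takes the analytic-signal angle.
    """
    spec = spec or ThetaFilterSpec()
    x = lfp_a.samples
    if lfp_b is not None:
        if lfp_b.rate != lfp_a.rate:
            raise ValueError("channel rates differ")
        x = x - lfp_b.samples
    b = kaiser_fir_bandpass(lfp_a.rate, *spec.band, spec.transition,
                            spec.pass_ripple_db, spec.stop_atten_db)
    if len(b) >= len(x):
        raise ValueError(
            f"trace too short for the requested filter (needs > {len(b)} samples)")
    filt = filtfilt_fir(b, x)
    from scipy.fft import next_fast_len
    analytic = sps.hilbert(filt, N=next_fast_len(len(filt)))[:len(filt)]
    return SignalTrace(np.angle(analytic), lfp_a.rate, "theta_phase", lfp_a.t0)


# ------------------------------------------------------ circular statistics

@dataclass
class PhaseLockResult:
    phases: np.ndarray
    r: float
    mean_phase: float
    z: float
    p: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_dropped: int = 0


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity; returns (Z, p).

    Z = n r^2; p uses the standard finite-n series approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n r.
    """
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    if n == 0:
        raise ValueError("no phases")
    r = np.abs(np.mean(np.exp(1j * phases)))
    big_r = n * r
    z = n * r ** 2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - big_r ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def phase_locking(phase: SignalTrace, events, n_bins: int = 18) -> PhaseLockResult:
    """Resultant vector length, mean phase and Rayleigh test of event phases.

    ``events`` is an EventTable or array of times; phases are read off the
    phase trace at the nearest sample.  Events where the phase trace is
    NaN (e.g. outside REM) are dropped and counted.
    """
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("no events")
    idx = np.clip(np.round((times - phase.t0) * phase.rate).astype(int),
                  0, len(phase.samples) - 1)
    ph = phase.samples[idx]
    keep = np.isfinite(ph)
    n_dropped = int(np.sum(~keep))
    ph = ph[keep]
    if len(ph) == 0:
        raise ValueError("all events fall where the phase trace is undefined")
    vec = np.mean(np.exp(1j * ph))
    r = float(np.abs(vec))
    mu = float(np.angle(vec))
    z, p = rayleigh_test(ph)
    counts, edges = np.histogram(ph, bins=n_bins, range=(-np.pi, np.pi))
    return PhaseLockResult(ph, r, mu, z, p, counts, edges, n_dropped)


# ------------------------------------------------------------- band power

def band_power_trace(lfp_a: SignalTrace, lfp_b: SignalTrace | None,
                     band: tuple[float, float],
                     window: float | None = None) -> SignalTrace:
    """Band-limited power (squared sliding RMS) at the input rate.

    The RMS window defaults to 20 ms for high-frequency bands (>= 50 Hz
    low edge, e.g. ripple) and one cycle of the band's low edge otherwise
    (e.g. theta).
    """
    x = lfp_a.samples
    if lfp_b is not None:
        x = x - lfp_b.samples
    lo, hi = band
    filt = butter_bandpass(x, lfp_a.rate, lo, hi)
    if window is None:
        window = 0.020 if lo >= 50 else 1.0 / lo
    env = sliding_rms(filt, lfp_a.rate, window)
    return SignalTrace(env * env, lfp_a.rate, f"{lfp_a.label}[{lo}-{hi}Hz power]", lfp_a.t0)


def _event_aligned(trace: SignalTrace, times: np.ndarray,
                   window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    pre, post = window
    n_pre = int(round(-pre * trace.rate))
    n_post = int(round(post * trace.rate))
    lags = np.arange(-n_pre, n_post + 1) / trace.rate
    rows = []
    for t in times:
        i = int(round((t - trace.t0) * trace.rate))
        if i - n_pre < 0 or i + n_post + 1 > len(trace.samples):
            continue
        rows.append(trace.samples[i - n_pre:i + n_post + 1])
    if not rows:
        raise ValueError("no complete event window inside the trace")
    return np.vstack(rows), lags


def event_power_xcorr(power: SignalTrace, events,
                      window: tuple[float, float] = (-3.0, 3.0),
                      baseline: tuple[float, float] = (-3.0, -2.0)
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-triggered average of a band-power trace, z-scored on a
    pre-event baseline segment of the averaged profile.

    Returns (lags, z-profile, raw mean profile).
    """
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    mat, lags = _event_aligned(power, times, window)
    mean = mat.mean(axis=0)
    bmask = (lags >= baseline[0]) & (lags <= baseline[1])
    if not bmask.any():
        raise ValueError("baseline segment outside the analysis window")
    mu = mean[bmask].mean()
    sd = mean[bmask].std()
    z = (mean - mu) / sd if sd > 0 else np.zeros_like(mean)
    return lags, z, mean


# ------------------------------------------------ asymmetry / modulation

@dataclass
class IndexResult:
    """(post - pre)/(post + pre); negative means lower after the event."""

    pre: float
    post: float
    index: float
    halfwidth: float = 0.25
    unit_id: str | None = None


def _pre_post_means(trace: SignalTrace, times: np.ndarray,
                    halfwidth: float) -> tuple[float, float]:
    n_h = int(round(halfwidth * trace.rate))
    pres, posts = [], []
    for t in times:
        i = int(round((t - trace.t0) * trace.rate))
        if i - n_h < 0 or i + n_h + 1 > len(trace.samples):
            continue
        pres.append(trace.samples[i - n_h:i].mean())
        posts.append(trace.samples[i + 1:i + n_h + 1].mean())
    if not pres:
        raise ValueError("no complete event window inside the trace")
    return float(np.mean(pres)), float(np.mean(posts))


def _make_index(pre: float, post: float, halfwidth: float,
                unit_id: str | None = None) -> IndexResult:
    tot = pre + post
    idx = (post - pre) / tot if tot > 0 else float("nan")
    return IndexResult(pre, post, idx, halfwidth, unit_id)


def asymmetry_index(power: SignalTrace, events,
                    halfwidth: float = 0.25) -> IndexResult:
    """Normalized pre/post difference of a power trace around event times.

    Pre/post means are averaged across events before indexing; the index
    is NaN when pre + post = 0 (undefined).
    """
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    pre, post = _pre_post_means(power, times, halfwidth)
    return _make_index(pre, post, halfwidth)


def modulation_index(spikes: list[SpikeTrain], events,
                     halfwidth: float = 0.25) -> list[IndexResult]:
    """Per-unit normalized pre/post firing-rate difference around events."""
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("no events")
    out = []
    for tr in spikes:
        pre_counts = post_counts = 0
        for t in times:
            pre_counts += np.sum((tr.times >= t - halfwidth) & (tr.times < t))
            post_counts += np.sum((tr.times > t) & (tr.times <= t + halfwidth))
        denom = len(times) * halfwidth
        out.append(_make_index(pre_counts / denom, post_counts / denom,
                               halfwidth, tr.unit_id))
    return out


def theta_power_windows(power: SignalTrace, events,
                        far: tuple[float, float] = (-1.0, -0.5),
                        near: tuple[float, float] = (-0.25, 0.25)
                        ) -> tuple[float, float]:
    """Mean band power in a remote pre-event window vs an event-centred
    window, averaged across events; paired across recordings upstream."""
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    lo = min(far[0], near[0])
    hi = max(far[1], near[1])
    mat, lags = _event_aligned(power, times, (lo, hi))
    mean = mat.mean(axis=0)
    m_far = float(mean[(lags >= far[0]) & (lags <= far[1])].mean())
    m_near = float(mean[(lags >= near[0]) & (lags <= near[1])].mean())
    return m_far, m_near


# ------------------------------------------------------------------ PETH

@dataclass
class PethResult:
    rates: np.ndarray          # units x bins, raw rate (Hz)
    z: np.ndarray              # units x bins, z-scored per unit
    lags: np.ndarray           # bin centers (s)
    unit_ids: list
    order_peak: np.ndarray     # unit order by peak latency
    order_pc: np.ndarray       # unit order by first-PC score
    silent_units: list = field(default_factory=list)


def peth(spikes: list[SpikeTrain], events,
         window: tuple[float, float] = (-1.0, 1.0),
         bin_width: float = 0.010,
         smooth_sd: float | None = 0.020) -> PethResult:
    """Peri-event time histograms, z-scored per unit over the window.

    Each unit's event-aligned spike rate is optionally smoothed with a
    Gaussian kernel (display convention) and normalized to zero mean /
    unit SD across its own profile.  Units with no spikes in any window
    yield a flat zero row and are flagged.  Two sort orders are returned:
    by peak-bin latency and by first principal-component score.
    """
    if bin_width <= 0:
        raise ValueError("bin must be > 0")
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("no events")
    pre, post = window
    edges = np.arange(pre, post + bin_width / 2, bin_width)
    lags = (edges[:-1] + edges[1:]) / 2
    n_units = len(spikes)
    rates = np.zeros((n_units, len(lags)))
    silent = []
    for u, tr in enumerate(spikes):
        rel = []
        for t in times:
            lo = np.searchsorted(tr.times, t + pre)
            hi = np.searchsorted(tr.times, t + post)
            rel.append(tr.times[lo:hi] - t)
        rel = np.concatenate(rel) if rel else np.array([])
        if len(rel) == 0:
            silent.append(tr.unit_id)
            continue
        counts, _ = np.histogram(rel, bins=edges)
        rates[u] = counts / (len(times) * bin_width)
    if smooth_sd:
        sig = smooth_sd / bin_width
        m = int(np.ceil(4 * sig))
        k = np.exp(-0.5 * (np.arange(-m, m + 1) / sig) ** 2)
        k /= k.sum()
        rates = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, rates)
    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (rates - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    order_peak = np.argsort(np.argmax(z, axis=1), kind="stable")
    if n_units >= 2:
        centered = z - z.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        order_pc = np.argsort(centered @ vt[0], kind="stable")
    else:
        order_pc = np.arange(n_units)
    return PethResult(rates, z, lags, [tr.unit_id for tr in spikes],
                      order_peak, order_pc, silent)


def profile_similarity(peth_a: np.ndarray, peth_b: np.ndarray
                       ) -> tuple[np.ndarray, float, float, int]:
    """Per-unit Pearson r between two PETH matrices + one-sample t vs 0.

    Units with zero variance in either profile are excluded (count
    returned).  Returns (r per included unit, t, p, n_excluded).
    """
    a = np.asarray(peth_a, dtype=float)
    b = np.asarray(peth_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("PETH matrices must share shape (equal binning)")
    rs, excluded = [], 0
    for ra, rb in zip(a, b):
        if ra.std() == 0 or rb.std() == 0:
            excluded += 1
            continue
        rs.append(np.corrcoef(ra, rb)[0, 1])
    rs = np.asarray(rs)
    if len(rs) < 2:
        return rs, float("nan"), float("nan"), excluded
    t, p = spstats.ttest_1samp(rs, 0.0)
    return rs, float(t), float(p), excluded


# -------------------------------------------------------- episode profile

def episode_quartile_profile(events: EventTable, episodes: list[StateEpisode],
                             state: str) -> np.ndarray:
    """Event rate in four equal normalized time bins across episodes of one
    state (rates per bin averaged over episodes)."""
    eps = [ep for ep in episodes if ep.state == state]
    if not eps:
        raise ValueError(f"no {state} episodes")
    t = events.times
    profiles = []
    for ep in eps:
        inside = t[(t >= ep.onset) & (t < ep.offset)]
        x = (inside - ep.onset) / ep.duration
        counts, _ = np.histogram(x, bins=4, range=(0.0, 1.0))
        profiles.append(counts / (ep.duration / 4.0))
    return np.mean(profiles, axis=0)


# ----------------------------------------------------------------- SDR

def _sdr_pair(sxx: np.ndarray, syy: np.ndarray, eps: float) -> tuple[float, float]:
    mx = sxx >= eps * sxx.max()
    my = syy >= eps * syy.max()
    rho_xy = syy.mean() / (sxx.mean() * np.mean(syy[mx] / sxx[mx]))
    rho_yx = sxx.mean() / (syy.mean() * np.mean(sxx[my] / syy[my]))
    return float(rho_xy), float(rho_yx)


def sdr(x_lfp: SignalTrace, y_lfp: SignalTrace, events,
        halfwidth: float = 0.25, nperseg: int = 128,
        eps: float = 1e-6) -> tuple[pd.DataFrame, dict]:
    """Spectral dependency ratio in +/- halfwidth windows around events.

    For each event, Welch PSDs of the X and Y snippets give S_XX and
    S_YY; with <.> the average over frequencies,

        rho_X->Y = <S_YY> / (<S_XX> . <S_YY / S_XX>)

    and symmetrically for Y->X.  A larger rho marks the stronger
    directional influence; identical snippets give exactly (1, 1), and
    the statistic is invariant to rescaling either trace.  Frequencies
    where the denominator PSD is below ``eps`` of its maximum are
    excluded from the ratio average; degenerate (all-zero) snippets are
    skipped and counted.

    Returns (per-event frame with rho_xy/rho_yx, summary dict).
    """
    if x_lfp.rate != y_lfp.rate:
        raise ValueError("traces must share a sampling rate")
    times = events.times if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    n_h = int(round(halfwidth * x_lfp.rate))
    rows, skipped = [], 0
    for t in times:
        ix = int(round((t - x_lfp.t0) * x_lfp.rate))
        iy = int(round((t - y_lfp.t0) * y_lfp.rate))
        if ix - n_h < 0 or ix + n_h + 1 > len(x_lfp.samples) \
                or iy - n_h < 0 or iy + n_h + 1 > len(y_lfp.samples):
            skipped += 1
            continue
        xs = x_lfp.samples[ix - n_h:ix + n_h + 1]
        ys = y_lfp.samples[iy - n_h:iy + n_h + 1]
        seg = min(nperseg, len(xs))
        _, sxx = sps.welch(xs, fs=x_lfp.rate, nperseg=seg, noverlap=seg // 2)
        _, syy = sps.welch(ys, fs=y_lfp.rate, nperseg=seg, noverlap=seg // 2)
        if sxx.max() <= 0 or syy.max() <= 0:
            skipped += 1
            continue
        rho_xy, rho_yx = _sdr_pair(sxx, syy, eps)
        rows.append((t, rho_xy, rho_yx))
    df = pd.DataFrame(rows, columns=["time", "rho_xy", "rho_yx"])
    summary = {
        "n_events": len(df),
        "n_skipped": skipped,
        "mean_rho_xy": float(df["rho_xy"].mean()) if len(df) else float("nan"),
        "mean_rho_yx": float(df["rho_yx"].mean()) if len(df) else float("nan"),
        "frac_xy_preferred": float(np.mean(df["rho_xy"] > df["rho_yx"])) if len(df) else float("nan"),
    }
    return df, summary


# ------------------------------------------------- episode-duration model

@dataclass
class LMEResult:
    beta: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float
    n_obs: int
    n_groups: int


def episode_duration_model(durations, rates, recording_ids) -> LMEResult:
    """Random-intercept linear mixed model: episode duration ~ event rate.

    y = X beta + Z b + eps with a per-recording random intercept, fit by
    maximum likelihood via statsmodels MixedLM.  Returns the fixed-effect
    slope with its 95% CI and p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(durations, dtype=float)
    x = np.asarray(rates, dtype=float)
    g = np.asarray(recording_ids)
    if len(y) < 3 or len(np.unique(g)) < 2:
        raise ValueError("need >= 3 episodes across >= 2 recordings")
    if x.std() == 0:
        raise ValueError("singular design: predictor is constant")
    exog = sm.add_constant(x)
    res = sm.MixedLM(y, exog, groups=g).fit(reml=False)
    ci = np.asarray(res.conf_int())
    return LMEResult(beta=float(res.fe_params[1]), ci_low=float(ci[1, 0]),
                     ci_high=float(ci[1, 1]), p=float(res.pvalues[1]),
                     intercept=float(res.fe_params[0]), n_obs=len(y),
                     n_groups=len(np.unique(g)))
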