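"""Synthetic sleep-session generator with known ground truth.

Builds multichannel sessions carrying the statistical structure the
analysis pipeline assumes — state-dependent Poisson P-waves with REM
clustering and von-Mises theta-phase locking, ~100 ms biphasic pontine
deflections, NREM ripple bursts (80-250 Hz) on 1/f background noise, REM
theta, wake EMG bursts, and interleaved-excitation photometry with
exponential bleaching and a shared motion artifact — so that every
detector and coupling statistic can be validated against injected truth.

Everything is deterministic given ``SessionConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._dsp import butter_bandpass, powerlaw_noise
from .core import NREM, REM, WAKE, Hypnogram, SignalTrace
from .photometry import PhotometrySession

__all__ = [
    "StateModel", "PWaveConfig", "RippleConfig", "ThetaConfig", "EMGConfig",
    "NoiseConfig", "PhotometryConfig", "SessionConfig",
    "GroundTruth", "SyntheticSession", "BilateralSession", "PhotometryTruth",
    "generate_session", "generate_bilateral", "generate_coupled_pair",
    "generate_photometry", "pwave_template",
]


# ---------------------------------------------------------------- configs

@dataclass
class StateModel:
    """Semi-Markov vigilance-state sequence: exponential episode durations
    rounded to whole epochs, with a WAKE -> NREM -> REM ordering bias."""

    mean_durations: dict = field(default_factory=lambda: {WAKE: 120.0, NREM: 160.0, REM: 60.0})
    epoch_len: float = 4.0
    p_nrem_to_rem: float = 0.6


@dataclass
class PWaveConfig:
    """State-dependent Poisson P-waves.

    ``amplitude_snr`` scales the biphasic template trough as a multiple of
    the 5-30 Hz filtered RMS of the background differential noise, so
    detectability is controlled directly.  During REM, event times are
    nudged so the session theta phase at each event follows a von Mises
    (``theta_mu``, ``theta_kappa``) distribution.  ``rem_ramp`` tilts the
    within-episode event density linearly (0 = homogeneous, 2 = density
    rising from 0 to twice the mean across the episode).
    """

    rates: dict = field(default_factory=lambda: {WAKE: 0.0, NREM: 0.09, REM: 0.8})
    doublet_prob: float = 0.25
    doublet_spacing: float = 0.15
    #: filtered trough depth as a multiple of the 5-30 Hz noise RMS; the
    #: default places the trough at roughly twice the mean + 5 SD envelope
    #: threshold, matching the visual prominence of real P-waves.
    amplitude_snr: float = 8.0
    width: float = 0.1
    theta_mu: float = 1.0
    theta_kappa: float = 1.0
    rem_ramp: float = 0.0
    min_separation: float = 0.12


@dataclass
class RippleConfig:
    """NREM-dominant ripple bursts: Hann-windowed sinusoid on a slow
    sharp-wave deflection.  ``amplitude_snr`` is relative to the 80-250 Hz
    filtered RMS of the hippocampal background noise.

    Decoy bursts (too short / too long for the duration filter) are
    injected as negative controls; short decoys carry less energy, as real
    spurious transients do.  ``pwave_sync_prob`` relocates that fraction of
    NREM P-waves into the middle of a ripple; with ``truncate_on_pwave``
    the co-occurring ripple is cut short just after the P-wave, emulating
    ripple termination by pontine input.
    """

    center_freq: float = 150.0
    rates: dict = field(default_factory=lambda: {WAKE: 0.0, NREM: 0.5, REM: 0.02})
    dur_range: tuple = (0.04, 0.12)
    amplitude_snr: float = 12.0
    sharp_wave_amp: float = 2.0
    decoy_short_count: int = 8
    decoy_short_dur: float = 0.010
    decoy_short_snr: float = 6.0
    decoy_long_count: int = 8
    decoy_long_dur: float = 0.250
    pwave_sync_prob: float = 0.0
    truncate_on_pwave: bool = False
    truncation_offset: float = 0.010


@dataclass
class ThetaConfig:
    """REM theta oscillation on the hippocampal channel; ``amplitude_snr``
    is relative to the 4-10 Hz filtered RMS of the background noise."""

    freq: float = 7.0
    amplitude_snr: float = 4.0
    vol_conduction: float = 0.3


@dataclass
class EMGConfig:
    """Neck EMG: a mains-locked pickup component plus broadband noise,
    amplitude-modulated by slow muscle tone, with phasic movement bursts
    during WAKE.  The composition mirrors quiet-sleep EMG, where the
    short-window RMS varies with physiological tone and line pickup rather
    than with the RMS estimator's own sampling noise.
    """

    burst_rate: float = 0.2
    burst_dur: tuple = (0.5, 2.0)
    burst_snr: float = 4.0
    tone_sd: float = 0.15
    tone_freq: float = 0.1
    hum_freq: float = 50.0
    hum_share: float = 0.8
    #: state-dependent tone levels: elevated in WAKE, reference in NREM,
    #: reduced in REM (atonia)
    tone_by_state: dict = field(default_factory=lambda: {WAKE: 1.3, NREM: 1.0, REM: 0.6})


@dataclass
class NoiseConfig:
    alpha: float = 1.0
    sd: float = 1.0


@dataclass
class PhotometryConfig:
    """Interleaved 470/405 nm photometry at a 40 Hz effective rate."""

    duration: float = 600.0
    rate: float = 40.0
    bleach_amp: float = 5.0
    bleach_tau: float = 600.0
    bleach_offset: float = 1.0
    transient_rate: float = 0.05
    transient_amp: float = 0.3
    tau_rise: float = 0.1
    tau_decay: float = 1.5
    artifact_sd: float = 0.05
    artifact_scale_405: float = 0.8
    noise_sd: float = 0.01


@dataclass
class SessionConfig:
    duration: float = 3600.0
    rate: float = 1000.0
    seed: int = 0
    states: StateModel = field(default_factory=StateModel)
    pwave: PWaveConfig = field(default_factory=PWaveConfig)
    ripple: RippleConfig = field(default_factory=RippleConfig)
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    emg: EMGConfig = field(default_factory=EMGConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    photometry: PhotometryConfig = field(default_factory=PhotometryConfig)

    def validate(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be > 0")
        for name, rates in (("pwave", self.pwave.rates), ("ripple", self.ripple.rates)):
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"{name} rates must be >= 0")
        if self.pwave.theta_kappa < 0:
            raise ValueError("theta_kappa must be >= 0")
        if not 0 <= self.ripple.pwave_sync_prob <= 1:
            raise ValueError("pwave_sync_prob must be in [0, 1]")
        if any(d <= 0 for d in self.states.mean_durations.values()):
            raise ValueError("mean episode durations must be > 0")
        if not 0 <= self.pwave.rem_ramp <= 2:
            raise ValueError("rem_ramp must be in [0, 2]")
        if self.ripple.center_freq >= self.rate / 2:
            raise ValueError("ripple center frequency must be below Nyquist")


# ---------------------------------------------------------------- outputs

@dataclass
class GroundTruth:
    """Everything injected into a synthetic session."""

    pwave_times: np.ndarray
    ripples: pd.DataFrame          # columns onset, offset, duration, truncated
    decoys_short: pd.DataFrame
    decoys_long: pd.DataFrame
    theta_phase: SignalTrace       # wrapped phase, NaN outside REM
    emg_bursts: pd.DataFrame       # columns onset, offset


@dataclass
class SyntheticSession:
    signals: dict
    hypnogram: Hypnogram
    truth: GroundTruth
    config: SessionConfig


@dataclass
class BilateralSession:
    times_left: np.ndarray
    times_right: np.ndarray
    signals: dict
    hypnogram: Hypnogram
    truth_left: GroundTruth


@dataclass
class PhotometryTruth:
    transient_times: np.ndarray
    transient_amp: float
    bleach_amp: float
    bleach_tau: float
    bleach_offset: float
    artifact: np.ndarray


# ------------------------------------------------------------- waveforms

def _scaled_pwave_template(rate: float, width: float, snr: float,
                           band_rms: float) -> np.ndarray:
    """P-wave template scaled so that its trough depth *after* the 5-30 Hz
    detection filter equals ``snr`` times the filtered background RMS
    (the filter attenuates the sharp trough, so scaling the raw template
    would understate the operative signal-to-noise ratio)."""
    tmpl = pwave_template(rate, width)
    padded = np.concatenate([np.zeros(int(rate)), tmpl, np.zeros(int(rate))])
    filt_depth = abs(butter_bandpass(padded, rate, 5.0, 30.0).min())
    return tmpl * (snr * band_rms / filt_depth)


def pwave_template(rate: float, width: float = 0.1) -> np.ndarray:
    """Trough-dominant biphasic pulse (difference of Gaussians), total
    visible width ~ ``width`` seconds, trough normalized to -1 at center."""
    half = 0.6 * width
    t = np.arange(-half, half + 1.0 / rate / 2, 1.0 / rate)
    s1 = 0.12 * width
    s2 = 0.15 * width
    w = -np.exp(-t ** 2 / (2 * s1 ** 2)) + 0.35 * np.exp(-(t - 0.28 * width) ** 2 / (2 * s2 ** 2))
    return w / abs(w.min())


def _add_at(x: np.ndarray, rate: float, t0: float, t: float, wave: np.ndarray,
            center: int | None = None) -> None:
    """Add ``wave`` to x aligned so wave[center] lands at time t (in place)."""
    if center is None:
        center = len(wave) // 2
    i = int(round((t - t0) * rate)) - center
    a = max(i, 0)
    b = min(i + len(wave), len(x))
    if b > a:
        x[a:b] += wave[a - i:b - i]


def _ripple_burst(rate: float, dur: float, freq: float, phase: float,
                  taper: float = 0.3) -> np.ndarray:
    """Tukey-windowed sinusoid.  A short taper keeps burst onset/offset
    sharply defined, so the injected span is a meaningful ground truth for
    boundary-timing checks (a full raised-cosine envelope would leave the
    effective onset ambiguous by tens of ms)."""
    n = max(int(round(dur * rate)), 4)
    t = np.arange(n) / rate
    return sps.windows.tukey(n, taper) * np.sin(2 * np.pi * freq * t + phase)


# ------------------------------------------------------- state sequence

def _draw_hypnogram(cfg: SessionConfig, rng: np.random.Generator) -> Hypnogram:
    sm = cfg.states
    n_epochs = int(np.ceil(cfg.duration / sm.epoch_len))
    labels: list[str] = []
    state = WAKE
    while len(labels) < n_epochs:
        d = rng.exponential(sm.mean_durations[state])
        k = max(1, int(round(d / sm.epoch_len)))
        labels.extend([state] * k)
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < sm.p_nrem_to_rem else WAKE
        else:
            state = WAKE
    return Hypnogram(np.array(labels[:n_epochs]), epoch_len=sm.epoch_len, t0=0.0)


def _thin_min_separation(times: np.ndarray, min_sep: float) -> np.ndarray:
    if len(times) == 0:
        return times
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= min_sep:
            keep.append(i)
    return times[keep]


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phase))


# ---------------------------------------------------------- main driver

def generate_session(cfg: SessionConfig) -> SyntheticSession:
    """Generate a full synthetic session (signals, hypnogram, ground truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate
    n = int(round(cfg.duration * rate))
    dur = n / rate

    hyp = _draw_hypnogram(cfg, rng)
    episodes = hyp.episodes()

    sd = cfg.noise.sd
    alpha = cfg.noise.alpha
    pons_a = powerlaw_noise(n, rate, alpha, sd, rng)
    pons_b = powerlaw_noise(n, rate, alpha, sd, rng)
    hpc_a = powerlaw_noise(n, rate, alpha, sd, rng)
    hpc_b = powerlaw_noise(n, rate, alpha, sd, rng)
    # EMG baseline: slow tonic amplitude modulation on hum + broadband noise.
    sos_tone = sps.butter(2, cfg.emg.tone_freq, btype="lowpass", fs=rate, output="sos")
    tone = sps.sosfiltfilt(sos_tone, rng.standard_normal(n))
    tone_sd = tone.std()
    if tone_sd > 0:
        tone *= cfg.emg.tone_sd / tone_sd
    t_all = np.arange(n) / rate
    hum = cfg.emg.hum_share * np.sqrt(2.0) * np.sin(
        2 * np.pi * cfg.emg.hum_freq * t_all + rng.uniform(0, 2 * np.pi))
    broadband = np.sqrt(max(1.0 - cfg.emg.hum_share ** 2, 0.0)) * rng.standard_normal(n)
    # State-dependent tone level (REM atonia), smoothed over ~2 s.
    level = np.empty(n)
    for ep in episodes:
        i0, i1 = int(round(ep.onset * rate)), min(int(round(ep.offset * rate)), n)
        level[i0:i1] = cfg.emg.tone_by_state.get(ep.state, 1.0)
    k_sm = np.hanning(int(2.0 * rate))
    level = np.convolve(level, k_sm / k_sm.sum(), mode="same")
    emg = np.maximum(level * (1.0 + tone), 0.1) * (hum + broadband) * sd

    # Reference RMS levels in the detection bands, measured on the noise
    # itself so amplitude_snr has a fixed operational meaning.
    diff_rms = butter_bandpass(pons_a - pons_b, rate, 5.0, 30.0).std()
    hi = min(250.0, rate / 2 * 0.9)
    ripple_rms = butter_bandpass(hpc_a, rate, 80.0, hi).std()
    theta_rms = butter_bandpass(hpc_a, rate, 4.0, 10.0).std()

    # --- theta on the hippocampal pair (REM only), phase truth recorded
    theta_phase = np.full(n, np.nan)
    theta_amp = cfg.theta.amplitude_snr * theta_rms
    f_theta = cfg.theta.freq
    for ep in episodes:
        if ep.state != REM:
            continue
        i0, i1 = int(round(ep.onset * rate)), int(round(ep.offset * rate))
        t_rel = np.arange(i1 - i0) / rate
        phi = 2 * np.pi * f_theta * t_rel
        env = np.ones(i1 - i0)
        ramp = min(int(0.5 * rate), (i1 - i0) // 4)
        if ramp > 1:
            w = np.hanning(2 * ramp)
            env[:ramp] = w[:ramp]
            env[-ramp:] = w[ramp:]
        wave = theta_amp * env * np.cos(phi)
        hpc_a[i0:i1] += wave
        hpc_b[i0:i1] += cfg.theta.vol_conduction * wave
        theta_phase[i0:i1] = _wrap(phi)

    # --- ripple bursts during NREM (plus rare REM ones)
    rip_on, rip_dur = [], []
    lo_d, hi_d = cfg.ripple.dur_range
    for ep in episodes:
        lam = cfg.ripple.rates.get(ep.state, 0.0)
        if lam <= 0 or ep.duration < 2.0:
            continue
        k = rng.poisson(lam * ep.duration)
        if k == 0:
            continue
        ons = np.sort(ep.onset + 0.5 + rng.random(k) * max(ep.duration - 1.0 - hi_d, 0.01))
        ds = rng.uniform(lo_d, hi_d, size=k)
        keep_t = []
        last_off = -np.inf
        for o, d in zip(ons, ds):
            if o - last_off >= 0.3:
                keep_t.append((o, d))
                last_off = o + d
        for o, d in keep_t:
            rip_on.append(o)
            rip_dur.append(d)
    rip_on = np.asarray(rip_on)
    rip_dur = np.asarray(rip_dur)
    rip_off = rip_on + rip_dur

    # --- P-wave times, state-dependent, phase-locked during REM
    pw_times = []
    for ep in episodes:
        lam = cfg.pwave.rates.get(ep.state, 0.0)
        if lam <= 0:
            continue
        k = rng.poisson(lam * ep.duration)
        if k == 0:
            continue
        u = rng.random(k)
        if ep.state == REM and cfg.pwave.rem_ramp > 0:
            r = cfg.pwave.rem_ramp
            a = 1.0 - r / 2.0
            x = (-a + np.sqrt(a * a + 2.0 * r * u)) / r
        else:
            x = u
        t = ep.onset + x * ep.duration
        if ep.state == REM:
            phi = 2 * np.pi * f_theta * (t - ep.onset)
            psi = rng.vonmises(cfg.pwave.theta_mu, cfg.pwave.theta_kappa, size=k)
            t = t + _wrap(psi - phi) / (2 * np.pi * f_theta)
        margin = min(0.3, ep.duration / 4)
        t = np.clip(t, ep.onset + margin, ep.offset - margin)
        dbl = rng.random(k) < cfg.pwave.doublet_prob
        t = np.concatenate([t, t[dbl] + cfg.pwave.doublet_spacing])
        t = t[(t > ep.onset) & (t < ep.offset - 0.05)]
        pw_times.append(t)
    pw_times = np.sort(np.concatenate(pw_times)) if pw_times else np.array([])
    pw_times = pw_times[(pw_times > 0.5) & (pw_times < dur - 0.5)]
    pw_times = _thin_min_separation(pw_times, cfg.pwave.min_separation)

    # Optionally relocate a fraction of NREM P-waves into ripples.
    if cfg.ripple.pwave_sync_prob > 0 and len(rip_on) and len(pw_times):
        nrem_mask = hyp.state_at(pw_times) == NREM
        cand = np.flatnonzero(nrem_mask & (rng.random(len(pw_times)) < cfg.ripple.pwave_sync_prob))
        k = min(len(cand), len(rip_on))
        if k:
            chosen = rng.choice(len(rip_on), size=k, replace=False)
            pw_times[cand[:k]] = rip_on[chosen] + 0.5 * rip_dur[chosen]
            pw_times = _thin_min_separation(np.sort(pw_times), cfg.pwave.min_separation)

    # Optionally truncate ripples co-occurring with a P-wave.
    truncated = np.zeros(len(rip_on), dtype=bool)
    if cfg.ripple.truncate_on_pwave and len(rip_on) and len(pw_times):
        for j in range(len(rip_on)):
            inside = pw_times[(pw_times > rip_on[j] + 0.005) & (pw_times < rip_off[j])]
            if len(inside):
                new_off = max(inside[0] + cfg.ripple.truncation_offset, rip_on[j] + 0.025)
                if new_off < rip_off[j]:
                    rip_off[j] = new_off
                    rip_dur[j] = new_off - rip_on[j]
                    truncated[j] = True

    # --- synthesize ripple waveforms (after truncation is final)
    rip_amp = cfg.ripple.amplitude_snr * ripple_rms
    for o, d in zip(rip_on, rip_dur):
        burst = rip_amp * _ripple_burst(rate, d, cfg.ripple.center_freq, rng.uniform(0, 2 * np.pi))
        _add_at(hpc_a, rate, 0.0, o, burst, center=0)
        _add_at(hpc_b, rate, 0.0, o, cfg.theta.vol_conduction * burst, center=0)
        sw_t = np.arange(-0.06, 0.06, 1.0 / rate)
        sw = -cfg.ripple.sharp_wave_amp * sd * np.exp(-sw_t ** 2 / (2 * 0.02 ** 2))
        _add_at(hpc_a, rate, 0.0, o + d / 2, sw)

    # --- decoy bursts in NREM, kept clear of real events
    def _place_decoys(count: int, d: float, snr: float) -> np.ndarray:
        placed = []
        occupied = list(zip(rip_on, rip_off))
        nrem_eps = [ep for ep in episodes if ep.state == NREM and ep.duration > 6.0]
        tries = 0
        while len(placed) < count and tries < 500 and nrem_eps:
            tries += 1
            ep = nrem_eps[rng.integers(len(nrem_eps))]
            o = rng.uniform(ep.onset + 1.0, ep.offset - 1.0 - d)
            if all(o + d + 1.0 < a or o > b + 1.0 for a, b in occupied):
                occupied.append((o, o + d))
                placed.append(o)
                burst = snr * ripple_rms * _ripple_burst(rate, d, cfg.ripple.center_freq,
                                                       rng.uniform(0, 2 * np.pi))
                _add_at(hpc_a, rate, 0.0, o, burst, center=0)
        return np.sort(np.asarray(placed))

    dec_s = _place_decoys(cfg.ripple.decoy_short_count, cfg.ripple.decoy_short_dur,
                          cfg.ripple.decoy_short_snr)
    dec_l = _place_decoys(cfg.ripple.decoy_long_count, cfg.ripple.decoy_long_dur,
                          cfg.ripple.amplitude_snr)

    # --- inject P-waveforms on the pontine pair
    tmpl = _scaled_pwave_template(rate, cfg.pwave.width, cfg.pwave.amplitude_snr, diff_rms)
    for t in pw_times:
        _add_at(pons_a, rate, 0.0, t, tmpl)

    # --- EMG bursts during WAKE
    emg_rows = []
    for ep in episodes:
        if ep.state != WAKE:
            continue
        k = rng.poisson(cfg.emg.burst_rate * ep.duration)
        for _ in range(k):
            d = rng.uniform(*cfg.emg.burst_dur)
            o = rng.uniform(ep.onset, max(ep.offset - d, ep.onset + 0.01))
            m = int(round(d * rate))
            i0 = int(round(o * rate))
            i1 = min(i0 + m, n)
            if i1 <= i0:
                continue
            env = np.hanning(i1 - i0)
            emg[i0:i1] += env * rng.standard_normal(i1 - i0) * cfg.emg.burst_snr * sd
            emg_rows.append((o, o + d))

    order = np.argsort(rip_on) if len(rip_on) else np.array([], dtype=int)
    ripples = pd.DataFrame({
        "onset": rip_on[order], "offset": rip_off[order],
        "duration": rip_dur[order], "truncated": truncated[order],
    })
    truth = GroundTruth(
        pwave_times=pw_times,
        ripples=ripples,
        decoys_short=pd.DataFrame({"onset": dec_s, "offset": dec_s + cfg.ripple.decoy_short_dur}),
        decoys_long=pd.DataFrame({"onset": dec_l, "offset": dec_l + cfg.ripple.decoy_long_dur}),
        theta_phase=_phase_trace(theta_phase, rate),
        emg_bursts=pd.DataFrame(emg_rows, columns=["onset", "offset"]),
    )
    signals = {
        "pons_a": SignalTrace(pons_a, rate, "pons_a"),
        "pons_b": SignalTrace(pons_b, rate, "pons_b"),
        "hpc_a": SignalTrace(hpc_a, rate, "hpc_a"),
        "hpc_b": SignalTrace(hpc_b, rate, "hpc_b"),
        "emg": SignalTrace(emg, rate, "emg"),
    }
    return SyntheticSession(signals, hyp, truth, cfg)


class _PhaseTrace(SignalTrace):
    """Phase trace that tolerates NaN outside REM episodes."""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


def _phase_trace(phase: np.ndarray, rate: float) -> SignalTrace:
    return _PhaseTrace(phase, rate, "theta_phase")


# ------------------------------------------------------------ bilateral

def generate_bilateral(cfg: SessionConfig, jitter_sd: float,
                       sync_prob: float) -> BilateralSession:
    """Two-hemisphere P-wave trains: a fraction ``sync_prob`` of left events
    is shared with the right hemisphere under Gaussian timing jitter; the
    remainder of the right train is drawn independently at matching
    state-dependent rates."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0 <= sync_prob <= 1:
        raise ValueError("sync_prob must be in [0, 1]")
    left = generate_session(cfg)
    rng = np.random.default_rng(cfg.seed + 104729)
    tl = left.truth.pwave_times
    shared = tl[rng.random(len(tl)) < sync_prob]
    shared = shared + rng.normal(0.0, jitter_sd, size=len(shared)) if len(shared) else shared

    indep = []
    for ep in left.hypnogram.episodes():
        lam = cfg.pwave.rates.get(ep.state, 0.0) * (1.0 - sync_prob)
        if lam <= 0:
            continue
        k = rng.poisson(lam * ep.duration)
        indep.append(ep.onset + rng.random(k) * ep.duration)
    tr = np.concatenate([shared] + indep) if indep else shared
    tr = np.sort(tr[(tr > 0.5) & (tr < cfg.duration - 0.5)])
    tr = _thin_min_separation(tr, cfg.pwave.min_separation)

    rate = cfg.rate
    n = len(left.signals["pons_a"].samples)
    rng2 = np.random.default_rng(cfg.seed + 224737)
    ra = powerlaw_noise(n, rate, cfg.noise.alpha, cfg.noise.sd, rng2)
    rb = powerlaw_noise(n, rate, cfg.noise.alpha, cfg.noise.sd, rng2)
    diff_rms = butter_bandpass(ra - rb, rate, 5.0, 30.0).std()
    tmpl = _scaled_pwave_template(rate, cfg.pwave.width, cfg.pwave.amplitude_snr, diff_rms)
    for t in tr:
        _add_at(ra, rate, 0.0, t, tmpl)
    signals = dict(left.signals)
    signals["pons_a_r"] = SignalTrace(ra, rate, "pons_a_r")
    signals["pons_b_r"] = SignalTrace(rb, rate, "pons_b_r")
    return BilateralSession(tl, tr, signals, left.hypnogram, left.truth)


# --------------------------------------------------------- coupled pair

def generate_coupled_pair(filter_spec: tuple, n: int, seed: int,
                          noise_sd: float = 0.1,
                          rate: float = 1000.0) -> tuple[SignalTrace, SignalTrace, dict]:
    """Directionally coupled pair: X is white noise, Y = filter(X) + noise.

    ``filter_spec`` is a ``(b, a)`` transfer function; it must be stable
    and causal.  The coefficients are returned as ground truth.
    """
    b, a = (np.atleast_1d(np.asarray(c, dtype=float)) for c in filter_spec)
    if len(a) > 1:
        roots = np.roots(a)
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError("unstable filter: poles on or outside the unit circle")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = sps.lfilter(b, a, x)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    truth = {"b": b, "a": a, "noise_sd": noise_sd}
    return SignalTrace(x, rate, "X"), SignalTrace(y, rate, "Y"), truth


# ----------------------------------------------------------- photometry

def _transient_kernel(rate: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    t = np.arange(0.0, 8.0 * tau_decay, 1.0 / rate)
    k = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return k / k.max()


def generate_photometry(cfg: PhotometryConfig,
                        seed: int = 0) -> tuple[PhotometrySession, PhotometryTruth]:
    """Interleaved-excitation photometry: the 470 nm channel carries
    calcium transients on an exponentially bleaching baseline plus a
    shared low-frequency motion artifact; the 405 nm isosbestic channel
    carries the bleaching and a scaled copy of the artifact but no
    transients."""
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate

    bleach = cfg.bleach_amp * np.exp(-t / cfg.bleach_tau) + cfg.bleach_offset

    if cfg.artifact_sd > 0:
        sos = sps.butter(2, 1.0, btype="lowpass", fs=cfg.rate, output="sos")
        art = sps.sosfiltfilt(sos, rng.standard_normal(n))
        art *= cfg.artifact_sd / art.std()
    else:
        art = np.zeros(n)

    k_tr = rng.poisson(cfg.transient_rate * cfg.duration)
    times = np.sort(rng.uniform(5.0, max(cfg.duration - 10.0, 5.0), size=k_tr))
    times = _thin_min_separation(times, 4.0 * cfg.tau_decay)
    kern = _transient_kernel(cfg.rate, cfg.tau_rise, cfg.tau_decay)
    transients = np.zeros(n)
    for tt in times:
        _add_at(transients, cfg.rate, 0.0, tt, cfg.transient_amp * kern, center=0)

    raw470 = bleach + transients + art + cfg.noise_sd * rng.standard_normal(n)
    raw405 = 0.85 * bleach + cfg.artifact_scale_405 * art + cfg.noise_sd * rng.standard_normal(n)

    session = PhotometrySession(pulse_times=t, raw_470=raw470, raw_405=raw405, rate=cfg.rate)
    truth = PhotometryTruth(times, cfg.transient_amp, cfg.bleach_amp, cfg.bleach_tau,
                            cfg.bleach_offset, art)
    return session, truth
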