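"""Shared signal-processing primitives.

Small wrappers around scipy.signal used by the detectors and the coupling
analyses: zero-phase Butterworth band-passes, Kaiser-window FIR design,
sliding / windowed RMS envelopes, and 1/f^alpha background noise.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = [
    "butter_bandpass",
    "kaiser_fir_bandpass",
    "fir_lowpass",
    "filtfilt_fir",
    "sliding_rms",
    "window_rms",
    "powerlaw_noise",
]


def butter_bandpass(x: np.ndarray, rate: float, low: float, high: float,
                    order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, SOS form)."""
    nyq = rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def kaiser_fir_bandpass(rate: float, low: float, high: float,
                        transition: float = 1.0,
                        pass_ripple_db: float = 0.01,
                        stop_atten_db: float = 50.0) -> np.ndarray:
    """Design a linear-phase Kaiser-window FIR band-pass.

    The Kaiser design couples pass-band ripple and stop-band attenuation
    through a single deviation parameter, so the stricter of the two
    requested tolerances is used.
    """
    delta_stop = 10.0 ** (-stop_atten_db / 20.0)
    delta_pass = 10.0 ** (pass_ripple_db / 20.0) - 1.0
    atten = -20.0 * np.log10(min(delta_stop, delta_pass))
    numtaps, beta = sps.kaiserord(atten, transition / (rate / 2.0))
    numtaps |= 1  # odd length -> exactly symmetric, integer group delay
    nyq = rate / 2.0
    if high >= nyq - transition:
        raise ValueError(
            f"band edge {high} Hz + transition {transition} Hz exceeds Nyquist "
            f"({nyq} Hz); need rate > {2 * (high + transition)} Hz"
        )
    return sps.firwin(numtaps, [low, high], window=("kaiser", beta),
                      pass_zero=False, fs=rate)


def fir_lowpass(rate: float, cutoff: float, numtaps: int | None = None) -> np.ndarray:
    """Linear-phase FIR low-pass (Hamming window)."""
    if numtaps is None:
        numtaps = int(4 * rate / cutoff) | 1
    return sps.firwin(numtaps | 1, cutoff, fs=rate)


def filtfilt_fir(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward application of a symmetric FIR filter.

    Uses FFT convolution (long Kaiser designs at kHz rates are far too slow
    through direct-form lfilter).  The input is odd-extended at both ends,
    as in scipy's filtfilt, to suppress edge transients.
    """
    b = np.asarray(b, dtype=float)
    n = len(b)
    if n % 2 == 0:
        raise ValueError("filter length must be odd (symmetric linear phase)")
    pad = min(3 * n, len(x) - 1)
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right])
    y = sps.fftconvolve(xp, b, mode="same")
    y = sps.fftconvolve(y[::-1], b, mode="same")[::-1]
    return y[pad:pad + len(x)]


def sliding_rms(x: np.ndarray, rate: float, window: float) -> np.ndarray:
    """Centered sliding-window RMS at sample stride.

    Edge windows are truncated: the divisor is the number of samples
    actually inside the window, so the envelope has the same length as x.
    """
    n = int(round(window * rate))
    if n < 2:
        raise ValueError(f"window {window}s is under 2 samples at {rate} Hz")
    half_l = n // 2
    half_r = n - half_l - 1
    c = np.concatenate([[0.0], np.cumsum(x * x, dtype=float)])
    idx = np.arange(len(x))
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r, len(x) - 1)
    sums = c[hi + 1] - c[lo]
    counts = hi - lo + 1
    return np.sqrt(sums / counts)


def window_rms(x: np.ndarray, rate: float, window: float) -> tuple[np.ndarray, float]:
    """Non-overlapping windowed RMS.

    Returns (values, output_rate) where output_rate = 1/window.  A trailing
    partial window is dropped.
    """
    n = int(round(window * rate))
    if n < 2:
        raise ValueError(f"window {window}s is under 2 samples at {rate} Hz")
    k = len(x) // n
    if k == 0:
        raise ValueError("trace shorter than one RMS window")
    seg = x[:k * n].reshape(k, n)
    return np.sqrt(np.mean(seg * seg, axis=1)), 1.0 / window


def powerlaw_noise(n: int, rate: float, alpha: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum, scaled to a target SD."""
    white = rng.standard_normal(n)
    if alpha == 0.0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / rate)
        scale = np.ones_like(f)
        nz = f > 0
        scale[nz] = f[nz] ** (-alpha / 2.0)
        scale[0] = 0.0  # no DC
        x = np.fft.irfft(spec * scale, n=n)
    s = x.std()
    if s > 0:
        x = x * (sd / s)
    return x
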