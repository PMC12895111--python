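"""Scalar phonatory descriptors: fundamental frequency, maximum glottal
area, phonation onset pressure, and sound pressure level.

F0 is estimated from the (area or acoustic) waveform by the autocorrelation
peak with parabolic sub-sample refinement; a short 0.02-s window gives
coarse 50-Hz FFT bins, which the interpolated autocorrelation avoids.
Non-oscillating records yield an *absent* (``None``) F0 rather than a
spurious value, mirroring stiff replicas that never phonate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt, welch

from .datatypes import AreaWaveform, SignalTrace
from .signal_ops import normalized_autocorr, parabolic_refine

#: standard acoustic reference pressure, Pa
P_REF = 20e-6


def estimate_f0(
    waveform,
    fs: float,
    *,
    max_lag_fraction: float = 0.6,
    min_height: float = 0.25,
    min_prominence: float = 0.05,
) -> float | None:
    """Fundamental frequency of a quasi-periodic waveform, Hz, or ``None``.

    The first autocorrelation peak whose height reaches 80% of the global
    peak is taken as the fundamental lag (guarding against octave errors)
    and refined parabolically.  Returns ``None`` when no peak exceeds
    ``min_height``: a constant or noise-only record has no oscillation.
    """
    if not fs > 0:
        raise ValueError(f"fs must be positive, got {fs}")
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("waveform must be a 1-D series with at least 4 samples")
    if np.std(x) < 1e-12 * max(1.0, abs(float(np.mean(x)))):
        return None

    max_lag = int(max_lag_fraction * len(x))
    acf = normalized_autocorr(x, max_lag)
    peaks, props = find_peaks(acf, height=min_height, prominence=min_prominence)
    peaks = peaks[peaks > 0]
    if len(peaks) == 0:
        return None
    heights = acf[peaks]
    candidates = peaks[heights >= 0.8 * heights.max()]
    lag = float(parabolic_refine(acf, int(candidates[0])))
    if lag <= 0:
        return None
    return fs / lag


def max_glottal_area(wave: AreaWaveform) -> float:
    """Maximum of the smoothed glottal area waveform, mm²."""
    if len(wave.area_smooth) == 0:
        raise ValueError("empty area waveform")
    return float(np.max(wave.area_smooth))


@dataclass(frozen=True)
class OnsetConfig:
    """Onset-detection settings.

    The oscillation envelope must exceed ``k`` times the pre-onset noise
    floor for at least ``m`` cycles; the floor is measured over the leading
    ``floor_fraction`` of the record (assumed pre-phonatory).
    """

    k: float = 5.0
    m: int = 3
    floor_fraction: float = 0.05
    band_halfwidth: float = 0.4  # bandpass half-width as a fraction of f_dom


def detect_onset_pressure(
    trace: SignalTrace, cfg: OnsetConfig | None = None
) -> float | None:
    """Phonation onset pressure from a subglottal pressure sweep, kPa.

    The slow ramp is removed, the dominant oscillation frequency located by
    Welch's method, the trace band-passed around it, and the Hilbert
    envelope compared against ``k`` times the pre-onset noise floor.  The
    onset pressure is the low-passed (ramp) value at the first instant the
    envelope stays above threshold for ``m`` cycles; returns ``None`` when
    the threshold is never sustained (no oscillation).
    """
    cfg = cfg or OnsetConfig()
    if trace.kind != "pressure":
        raise ValueError(f"onset detection needs a pressure trace, got kind={trace.kind!r}")
    x = trace.samples
    fs = trace.fs
    n = len(x)
    if n < 32:
        return None

    # remove the slow ramp before locating the oscillation band
    t = np.arange(n)
    coeffs = np.polyfit(t, x, 1)
    resid = x - np.polyval(coeffs, t)

    nperseg = min(n, 4096)
    freqs, psd = welch(resid, fs=fs, nperseg=nperseg)
    valid = freqs > 5.0 * fs / n  # ignore DC/ramp leakage
    if not valid.any():
        return None
    f_dom = float(freqs[valid][np.argmax(psd[valid])])
    if f_dom <= 0:
        return None

    lo = max(f_dom * (1 - cfg.band_halfwidth), 1e-3)
    hi = min(f_dom * (1 + cfg.band_halfwidth), 0.49 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sosfiltfilt(sos, resid)
    envelope = np.abs(hilbert(band))

    n_floor = max(32, int(cfg.floor_fraction * n))
    floor = float(np.median(envelope[:n_floor]))
    threshold = cfg.k * floor + 1e-12

    m_samples = max(1, int(round(cfg.m * fs / f_dom)))
    if m_samples >= n:
        return None
    sustained_min = minimum_filter1d(envelope, size=m_samples, mode="nearest")
    # index i such that envelope[i : i + m_samples] all exceed threshold
    start = m_samples // 2
    window_min = sustained_min[start : start + (n - m_samples + 1)]
    above = np.flatnonzero(window_min > threshold)
    if len(above) == 0:
        return None
    onset_idx = int(above[0])

    sos_lp = butter(2, max(f_dom / 5.0, 1.0 / trace.time[-1]), btype="lowpass", fs=fs, output="sos")
    baseline = sosfiltfilt(sos_lp, x)
    return float(baseline[onset_idx])


def spl(trace) -> float:
    """Sound pressure level, dB re 20 µPa, of a mean-removed acoustic trace."""
    if isinstance(trace, SignalTrace):
        if trace.kind != "acoustic":
            raise ValueError(f"SPL needs an acoustic trace, got kind={trace.kind!r}")
        x = trace.samples
    else:
        x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        raise ValueError("zero-power trace has no defined SPL")
    return 20.0 * np.log10(rms / P_REF)
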