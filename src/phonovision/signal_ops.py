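"""Small time-series primitives shared by the metric and motion modules:
normalized autocorrelation, sub-sample peak refinement, and fractional
cross-correlation delay."""

from __future__ import annotations

import numpy as np


def parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample position of a local maximum of ``y`` near index ``i``.

    Fits a parabola through (i-1, i, i+1); returns ``i`` unchanged at the
    array ends or for a degenerate (flat) neighbourhood.  The correction is
    clamped to half a sample to stay within the fitted interval.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def normalized_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased, variance-normalized autocorrelation for lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    acf = acf / counts
    if acf[0] <= 0:
        return np.zeros(max_lag + 1)
    return acf / acf[0]


def xcorr_delay(a: np.ndarray, b: np.ndarray, max_lag: int) -> float | None:
    """Fractional lag (samples) by which ``b`` trails ``a``.

    Maximizes the unbiased cross-correlation ``c(tau) = <a(t) b(t+tau)>``
    over ``|tau| <= max_lag`` with parabolic sub-sample refinement; positive
    means ``b`` reproduces ``a``'s features later in time.  Returns ``None``
    for degenerate (zero-variance) inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must share a length")
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        return None
    n = len(a)
    max_lag = int(min(max_lag, n - 2))
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            c[k] = np.dot(a[: n - lag], b[lag:]) / (n - lag)
        else:
            c[k] = np.dot(a[-lag:], b[: n + lag]) / (n + lag)
    i = int(np.argmax(c))
    return float(lags[0] + parabolic_refine(c, i))
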