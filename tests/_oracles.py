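"""Independent brute-force oracles used by the test suite.

Kept deliberately separate from the package implementation: plain normal
equations assembled by hand plus the t-distribution CDF, and a direct
discrete-Fourier magnitude scan for spectral checks.
"""

import math

import numpy as np
from scipy.special import betainc


def ols_oracle(x, y):
    """Simple linear regression via explicit normal equations.

    Returns (slope, intercept, r, p, slope_se, intercept_se) with the
    two-sided slope p-value from the t distribution with n-2 df, computed
    through the regularized incomplete beta function (no scipy.stats).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    syy = (y * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det

    ss_res = ((y - slope * x - intercept) ** 2).sum()
    ss_tot = syy - sy * sy / n
    ss_x = sxx - sx * sx / n
    r = (sxy - sx * sy / n) / math.sqrt(ss_x * ss_tot) if ss_tot > 0 else 0.0

    df = n - 2
    if ss_res <= 0:
        return slope, intercept, r, 0.0, 0.0, 0.0
    sigma2 = ss_res / df
    slope_se = math.sqrt(sigma2 / ss_x)
    intercept_se = math.sqrt(sigma2 * (1.0 / n + (sx / n) ** 2 / ss_x))
    t = slope / slope_se
    # two-sided p via I_{df/(df+t^2)}(df/2, 1/2)
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return slope, intercept, r, float(p), slope_se, intercept_se


def tone_amplitude(signal, fs, freq):
    """Amplitude of the ``freq`` component by least-squares projection onto
    sin/cos at that exact frequency (bin-alignment independent)."""
    x = np.asarray(signal, float)
    t = np.arange(len(x)) / fs
    c = np.cos(2 * np.pi * freq * t)
    s = np.sin(2 * np.pi * freq * t)
    a = 2.0 * np.dot(x, c) / len(x)
    b = 2.0 * np.dot(x, s) / len(x)
    return float(np.hypot(a, b))


def spectrum_peak(signal, fs, freq, half_bw=1.0):
    """Peak DFT magnitude within +/- half_bw Hz of ``freq`` (rFFT scan)."""
    x = np.asarray(signal, float)
    mags = np.abs(np.fft.rfft(x)) / len(x)
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    band = (f >= freq - half_bw) & (f <= freq + half_bw)
    return float(mags[band].max())
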