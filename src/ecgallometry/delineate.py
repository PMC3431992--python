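"""Fiducial-point delineation of a signal-averaged beat template.

Rules implemented:

* QRS onset/offset — search outward from R for the first region where the
  slope magnitude |dV/dt| stays below a threshold (a fraction of the peak
  in-QRS slope) for ``m`` consecutive samples;
* isoelectric level — median of all samples preceding QRS onset;
* P wave — peaks/valleys of a 9-point smoothed derivative in the pre-QRS
  window: P peak at the derivative zero crossing between its extrema,
  onset/end where the derivative magnitude falls below a noise-scaled
  threshold.  An absent P is a legal outcome, not an error;
* T wave — first significant local peak of either sign after QRS offset;
  a least-squares line fitted from the peak down the descending limb is
  intersected with the isoelectric level to give T end (tangent method);
* ST deviation — template amplitude 50 ms after QRS onset minus the
  isoelectric level.

Thresholds that the delineation rules leave open (slope fraction, run
length, significance multiples, tail extent) are keyword parameters with
the defaults documented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy import signal as sps

from .preprocess import BeatTemplate

__all__ = [
    "FiducialSet", "DelineationError",
    "find_qrs_bounds", "estimate_isoelectric", "delineate_p", "delineate_t",
    "measure_st", "delineate_template",
]


class DelineationError(RuntimeError):
    pass


@dataclass
class FiducialSet:
    """Landmark sample indices of one template (None = absent) plus the
    isoelectric level in mV.  ``st_point`` is the fixed-offset ST
    measurement sample (QRS onset + 50 ms)."""

    p_onset: int | None = None
    p_peak: int | None = None
    p_end: int | None = None
    qrs_onset: int | None = None
    q_trough: int | None = None
    r_peak: int | None = None
    s_trough: int | None = None
    qrs_end: int | None = None
    t_peak: int | None = None
    t_end: int | None = None
    st_point: int | None = None
    isoelectric_level: float = 0.0

    _ORDER = ("p_onset", "p_peak", "p_end", "qrs_onset", "q_trough", "r_peak",
              "s_trough", "qrs_end", "t_peak", "t_end")

    def validate(self) -> None:
        present = [getattr(self, n) for n in self._ORDER if getattr(self, n) is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise DelineationError("fiducial indices out of order")
        if not math.isfinite(self.isoelectric_level):
            raise DelineationError("isoelectric level not finite")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# --------------------------------------------------------------------------
# QRS bounds


def find_qrs_bounds(tpl: BeatTemplate, slope_frac: float = 0.05,
                    run_length: int = 3, search_ms: float = 80.0,
                    min_deflection: float = 0.02,
                    smooth_samples: int = 5) -> tuple[int, int]:
    """Slope-threshold QRS onset and offset around the template R peak.

    The slope is a short-boxcar-smoothed first difference (the smoothing
    keeps residual template noise well below the threshold); the threshold
    is ``slope_frac`` times the peak slope magnitude within the search
    window, and the bound is the first sample (moving away from R) where
    the slope magnitude stays below it for ``run_length`` consecutive
    samples, compensated for the smoothing half-width so noise-free corner
    onsets are recovered exactly.  Raises ``DelineationError`` for a flat
    template (peak-to-peak deflection below ``min_deflection`` mV in the
    window) or when no sub-threshold region exists within the window.
    """
    x = np.asarray(tpl.samples, float)
    r = tpl.r_index
    w = int(round(search_ms * tpl.fs / 1000.0))
    lo, hi = max(0, r - w), min(len(x), r + w + 1)
    if np.ptp(x[lo:hi]) < min_deflection:
        raise DelineationError("no QRS deflection")
    k = max(1, smooth_samples) | 1          # odd
    half = k // 2
    dv = np.convolve(np.diff(x), np.ones(k) / k, mode="same")
    theta = slope_frac * np.max(np.abs(dv[lo:hi - 1]))

    # leftward: find run_length consecutive sub-threshold slopes
    onset = None
    count = 0
    for j in range(r - 1, lo - 1, -1):
        if abs(dv[j]) < theta:
            count += 1
            if count == run_length:
                onset = j + run_length + half
                break
        else:
            count = 0
    # rightward
    end = None
    count = 0
    for j in range(r, hi - 1):
        if abs(dv[j]) < theta:
            count += 1
            if count == run_length:
                end = j - run_length + 1 - half
                break
        else:
            count = 0
    if onset is None or end is None:
        raise DelineationError("no sub-threshold slope region within the QRS window")
    if not onset < r < end:
        raise DelineationError("QRS bounds do not bracket the R peak")
    return onset, end


def estimate_isoelectric(tpl: BeatTemplate, qrs_onset: int) -> float:
    """Median of all template samples preceding QRS onset."""
    if qrs_onset <= 0:
        raise DelineationError("no samples precede QRS onset")
    return float(np.median(np.asarray(tpl.samples[:qrs_onset], float)))


# --------------------------------------------------------------------------
# P wave


_DERIV9 = np.array([-4.0, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0]) / 60.0


def _nine_point_derivative(x: np.ndarray) -> np.ndarray:
    """Smoothed 9-point derivative d[n] = sum_j j*(x[n+j]-x[n-j])/60."""
    return np.convolve(x, _DERIV9[::-1], mode="same")


def delineate_p(tpl: BeatTemplate, qrs_onset: int,
                noise_sd: float | None = None,
                deriv_frac: float = 0.10, run_length: int = 2,
                presence_mult: float = 6.0, edge_mult: float = 5.0,
                min_deriv: float = 5e-4,
                guard_samples: int = 6) -> tuple[int | None, int | None, int | None]:
    """P onset/peak/end from the 9-point derivative of the pre-QRS window.

    The window stops ``guard_samples`` (kernel half-width + margin) before
    QRS onset so the Q downstroke cannot leak into the derivative.  The P
    peak is the derivative zero crossing between its extremum pair; onset
    and end are where the derivative magnitude falls below
    ``max(deriv_frac * |d|_max, edge_mult * sigma_d)`` for ``run_length``
    samples, where ``sigma_d = noise_sd / sqrt(60)`` is the white-noise
    scale of the 9-point derivative (estimated from the window's median
    absolute deviation when ``noise_sd`` is not given).  A window whose
    derivative never exceeds ``max(presence_mult * sigma_d, min_deriv)``
    has no P: ``(None, None, None)`` — a legal outcome.
    """
    x = np.asarray(tpl.samples, float)
    end_w = qrs_onset - guard_samples
    if end_w < 9:
        return None, None, None
    d = _nine_point_derivative(x)[:end_w]
    d[:4] = 0.0                                  # kernel edge region
    if noise_sd is not None:
        sigma_d = noise_sd / math.sqrt(60.0)
    else:
        sigma_d = float(np.median(np.abs(d - np.median(d)))) / 0.6745
    dmax = float(np.max(np.abs(d)))
    if dmax < max(presence_mult * sigma_d, min_deriv):
        return None, None, None

    imax = int(np.argmax(d))
    imin = int(np.argmin(d))
    a, b = sorted((imax, imin))
    if a == b or d[a] == 0 or np.sign(d[a]) == np.sign(d[b]):
        return None, None, None

    # peak: zero crossing of the derivative between the extremum pair
    seg = d[a:b + 1]
    cross = np.where(np.diff(np.sign(seg)) != 0)[0]
    if len(cross) == 0:
        return None, None, None
    c = cross[0]
    # linear interpolation of the crossing, rounded to the nearest sample
    frac = seg[c] / (seg[c] - seg[c + 1])
    p_peak = a + c + int(round(frac))

    # the cap keeps an over-estimated noise scale from pulling both edges
    # inside the wave; the floor keeps noise from triggering outside it
    theta = min(max(deriv_frac * dmax, edge_mult * sigma_d), 0.3 * dmax)
    onset = None
    count = 0
    for j in range(a, 3, -1):
        if abs(d[j]) < theta:
            count += 1
            if count == run_length:
                onset = j + run_length
                break
        else:
            count = 0
    p_end = None
    count = 0
    for j in range(b, end_w):
        if abs(d[j]) < theta:
            count += 1
            if count == run_length:
                # -1 compensates the kernel tail, which keeps the
                # derivative above threshold ~1 sample past the true end
                p_end = j - run_length
                break
        else:
            count = 0
    if onset is None or p_end is None or not onset < p_peak < p_end:
        return None, None, None
    return onset, p_peak, p_end


# --------------------------------------------------------------------------
# T wave


def delineate_t(tpl: BeatTemplate, qrs_end: int, iso: float,
                noise_sd: float | None = None, noise_mult: float = 3.0,
                min_amplitude: float = 0.02, min_prominence: float = 0.006,
                prom_frac: float = 0.7, return_frac: float = 0.10,
                start_offset_ms: float = 4.0,
                smooth_samples: int = 5) -> tuple[int, int]:
    """T peak (first significant post-QRS extremum of either sign) and T end
    by the tangent method.

    Peaks are picked on a short-boxcar-smoothed trace with two gates:
    height |v - iso| >= ``max(noise_mult * noise_sd, min_amplitude)`` and
    local prominence >= ``max(noise_mult * noise_sd * sqrt(2/k),
    min_prominence)``.  A peak also only counts as *significant* when its
    prominence is at least ``prom_frac`` of the most prominent candidate in
    the window — height alone cannot discriminate a small T riding an
    elevated ST pedestal from a noise ripple on that pedestal, prominence
    can.  The earliest significant peak of either sign is the T peak,
    refined to the raw-sample extremum in its immediate neighbourhood.  A
    least-squares line is then fitted from the peak down the descending
    limb, up to the sample where the wave first returns to within
    ``return_frac`` of (peak - iso); its intersection with the isoelectric
    level, rounded to the nearest sample, is the T end.  Raises
    ``DelineationError`` when no significant peak exists.
    """
    x = np.asarray(tpl.samples, float)
    start = qrs_end + max(1, int(round(start_offset_ms * tpl.fs / 1000.0)))
    if start >= len(x) - 2:
        raise DelineationError("no samples after QRS end")
    k = max(1, smooth_samples)
    thr_h = min_amplitude if noise_sd is None else max(noise_mult * noise_sd,
                                                       min_amplitude)
    thr_p = min_prominence if noise_sd is None else \
        max(noise_mult * noise_sd * math.sqrt(2.0 / k), min_prominence)
    sm = np.convolve(x - iso, np.ones(k) / k, mode="same")
    seg = sm[start:]
    pos, pprop = sps.find_peaks(seg, prominence=thr_p)
    neg, nprop = sps.find_peaks(-seg, prominence=thr_p)
    cands = [(int(i), float(p)) for i, p in
             zip(np.concatenate([pos, neg]),
                 np.concatenate([pprop["prominences"], nprop["prominences"]]))
             if abs(seg[int(i)]) >= thr_h]
    if not cands:
        raise DelineationError("no T wave")
    max_prom = max(p for _, p in cands)
    t_peak = start + min(i for i, p in cands if p >= prom_frac * max_prom)
    # refine on a lightly smoothed trace (raw argmax jitters on flat apices)
    t_peak, _ = apex_amplitude(x, t_peak, iso)

    peak_amp = x[t_peak] - iso
    tail_end = None
    for j in range(t_peak + 1, len(x)):
        if abs(x[j] - iso) <= return_frac * abs(peak_amp):
            tail_end = j
            break
    if tail_end is None:
        tail_end = len(x) - 1
    if tail_end - t_peak < 2:
        raise DelineationError("T descending limb too short for the tangent fit")

    idx = np.arange(t_peak, tail_end + 1, dtype=float)
    a, b = np.polyfit(idx, x[t_peak:tail_end + 1], 1)
    if a == 0 or np.sign(a) == np.sign(peak_amp):
        raise DelineationError("T tail does not descend toward the baseline")
    t_end = int(round((iso - b) / a))
    t_end = max(t_end, t_peak + 1)
    t_end = min(t_end, len(x) - 1)
    return t_peak, t_end


# --------------------------------------------------------------------------
# ST and full delineation


def st_amplitude(samples: np.ndarray, i: int, iso: float = 0.0,
                 width: int = 5) -> float:
    """ST-level read at sample ``i``: median of the ``width`` samples from
    ``i`` rightward.  The ST segment extends to the right of the
    measurement point, so a forward window stays on the flat segment even
    when ``i`` falls exactly on the corner of the QRS terminal limb, and
    the median tolerates contamination by an early T upstroke."""
    x = np.asarray(samples, float)
    return float(np.median(x[i:min(len(x), i + width)]) - iso)


def apex_amplitude(samples: np.ndarray, t_peak: int, iso: float = 0.0,
                   slope_lag: int = 4) -> tuple[int, float]:
    """Corner-corrected T-apex read.

    The apex sits where two nearly linear limbs meet, so a plain sample
    read carries the full sample noise and any smoothed read is biased low
    by the local slopes.  This estimator takes the 3-sample-smoothed
    extremum near ``t_peak`` and adds back the first-order smoothing loss
    (a + b)/3, with the limb slopes a, b estimated over ``slope_lag``
    samples.  Returns (refined apex index, amplitude relative to iso).
    """
    x = np.asarray(samples, float)
    sgn = 1.0 if x[t_peak] - iso >= 0 else -1.0
    y = sgn * (x - iso)
    sm = np.convolve(y, np.ones(3) / 3.0, mode="same")
    # index: argmax of a raw-dominated blend (4*y + neighbours)/6 -- exact
    # at a noise-free corner whenever the fall slope is < 5x the rise slope,
    # while the neighbour terms damp pure-noise jitter on flat apices
    blend = (4.0 * y + np.roll(y, 1) + np.roll(y, -1)) / 6.0
    lo = max(1, t_peak - 3)
    hi = min(len(x) - 1, t_peak + 4)
    pk = lo + int(np.argmax(blend[lo:hi]))
    # amplitude: smoothed read plus first-order corner loss (a + b)/3
    a = max(0.0, (y[pk] - y[max(0, pk - slope_lag)]) / slope_lag)
    b = max(0.0, (y[pk] - y[min(len(x) - 1, pk + slope_lag)]) / slope_lag)
    return pk, float(sgn * (sm[pk] + (a + b) / 3.0))


def measure_st(tpl: BeatTemplate, qrs_onset: int, iso: float,
               offset_ms: float = 50.0) -> tuple[float, int]:
    """ST deviation: amplitude ``offset_ms`` after QRS onset minus the
    isoelectric level (forward-median read, see ``st_amplitude``).
    Returns (ST_A in mV, the sample used)."""
    i = qrs_onset + int(round(offset_ms * tpl.fs / 1000.0))
    if not 0 <= i < len(tpl.samples):
        raise DelineationError("ST measurement point outside the template")
    return st_amplitude(tpl.samples, i, iso), i


def delineate_template(tpl: BeatTemplate, amp_floor: float = 0.01,
                       **kwargs) -> FiducialSet:
    """Full delineation of one template.

    Runs QRS bounds, isoelectric level, P and T delineation and the ST
    measurement, then locates R as the positive extremum inside the QRS
    bounds and Q/S as the signed minima on either side of R (reported
    absent when shallower than ``amp_floor`` mV below the isoelectric
    level).  Extra keyword arguments are forwarded to the stage functions
    by prefix (``p_``, ``t_``, ``qrs_``).
    """
    x = np.asarray(tpl.samples, float)
    qrs_kw = {k[4:]: v for k, v in kwargs.items() if k.startswith("qrs_")}
    p_kw = {k[2:]: v for k, v in kwargs.items() if k.startswith("p_")}
    t_kw = {k[2:]: v for k, v in kwargs.items() if k.startswith("t_")}

    qrs_on, qrs_end = find_qrs_bounds(tpl, **qrs_kw)
    iso = estimate_isoelectric(tpl, qrs_on)
    # white-noise scale from the lower quartile of |first differences|:
    # robust to the P wave occupying a sizeable part of the pre-QRS window
    # (wave-slope differences land in the upper half of the distribution)
    pre = x[:qrs_on]
    noise_sd = float(np.percentile(np.abs(np.diff(pre)), 25.0)) / 0.4506 \
        if len(pre) > 5 else None

    p_on, p_pk, p_end = delineate_p(tpl, qrs_on, noise_sd=noise_sd, **p_kw)
    t_pk, t_end = delineate_t(tpl, qrs_end, iso, noise_sd=noise_sd, **t_kw)
    st_a, st_i = measure_st(tpl, qrs_on, iso)

    r = qrs_on + int(np.argmax(x[qrs_on:qrs_end + 1] - iso))
    q = qrs_on + int(np.argmin(x[qrs_on:r + 1])) if r > qrs_on else None
    s = r + int(np.argmin(x[r:qrs_end + 1])) if qrs_end > r else None
    if q is not None and (x[q] - iso > -amp_floor or q == qrs_on):
        q = None
    if s is not None and (x[s] - iso > -amp_floor or s == qrs_end):
        s = None
    # keep ordering strict: troughs must lie strictly between bounds and R
    if q is not None and not qrs_on < q < r:
        q = None
    if s is not None and not r < s < qrs_end:
        s = None

    fs_ = FiducialSet(p_onset=p_on, p_peak=p_pk, p_end=p_end,
                      qrs_onset=qrs_on, q_trough=q, r_peak=r, s_trough=s,
                      qrs_end=qrs_end, t_peak=t_pk, t_end=t_end,
                      st_point=st_i, isoelectric_level=iso)
    fs_.validate()
    return fs_
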