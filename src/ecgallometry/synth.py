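"""Synthetic rabbit ECG and infarct-cohort generation with exact ground truth.

Every downstream stage of the pipeline (template averaging, delineation,
parameter measurement, allometric fitting) is tested against waveforms and
cohorts produced here, so the generator is built for *exact* truths rather
than physiological fidelity:

* one beat is a Gaussian P wave, a piecewise-linear Q/R/S complex, a flat
  ST segment and a piecewise-linear (triangular) T wave.  All landmark
  times are snapped to the sample grid, so the returned fiducial indices
  are exact positions of the constructed corners, and the linear T tail
  makes the tangent-intersection T-end rule exactly well defined;
* a recording is a train of such beats with Gaussian RR variability plus
  independently switchable white noise, low-frequency baseline wander,
  50 Hz mains interference and occasional ectopic beats (scaled and
  widened copies that fail the cross-correlation gate by construction);
* a cohort is a set of animals whose per-parameter deviations from a
  healthy reference follow the allometric law

      log10|ECG_D - ECG_N| = delta + beta * log10(VIMn) + eps,

  eps ~ Normal(0, residual_sd), with VIMn = PIM * VM / HW the normalized
  ventricular infarcted mass.  Zero residual noise therefore makes the
  cohort generator the exact inverse of the allometric fitting module.

All times in morphology/config objects are milliseconds, amplitudes are
millivolts, sampling rates Hz.  Logarithms are base 10 throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .measure import PARAM_NAMES, QTC_NAMES, correct_qt

__all__ = [
    "BeatMorphology",
    "RecordingConfig",
    "CohortConfig",
    "AllometricStructure",
    "BeatFiducials",
    "RecordingTruth",
    "make_beat",
    "make_recording",
    "make_cohort",
    "make_template",
    "mi_morphology",
    "normal_morphology",
    "morphology_from_params",
    "NORMAL_REFERENCE",
    "STUDY_COEFFS",
]


# --------------------------------------------------------------------------
# domain types


@dataclass
class BeatMorphology:
    """Geometric description of a single P-QRS-T beat.

    Times are ms, amplitudes mV.  ``pr_interval`` runs from P onset to QRS
    onset; ``t_peak_time`` and ``t_end_time`` are measured from QRS offset.
    """

    p_amplitude: float = 0.06
    p_duration: float = 29.0
    pr_interval: float = 71.0
    q_amplitude: float = -0.50
    r_amplitude: float = 0.21
    s_amplitude: float = -0.12
    qrs_duration: float = 45.0
    st_offset: float = 0.08
    t_amplitude: float = 0.10
    t_peak_time: float = 78.0
    t_end_time: float = 137.0

    # fractions of qrs_duration at which the Q trough, R peak and S trough sit
    q_frac: float = 0.20
    r_frac: float = 0.45
    s_frac: float = 0.70
    # fraction of t_peak_time at which the T upstroke leaves the ST segment
    t_rise_frac: float = 0.50

    def validate(self) -> None:
        for name in ("p_duration", "pr_interval", "qrs_duration",
                     "t_peak_time", "t_end_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.t_end_time <= self.t_peak_time:
            raise ValueError("t_end_time must exceed t_peak_time")
        if self.pr_interval < self.p_duration:
            raise ValueError("pr_interval must cover the P wave")
        if self.q_amplitude > 0 or self.s_amplitude > 0:
            raise ValueError("Q and S amplitudes are signed negative (<= 0)")
        if self.r_amplitude < 0:
            raise ValueError("R amplitude must be >= 0")
        if not 0 < self.q_frac < self.r_frac < self.s_frac < 1:
            raise ValueError("QRS landmark fractions must be ordered in (0, 1)")

    @property
    def duration(self) -> float:
        """Total beat support in ms (P onset to T end)."""
        return self.pr_interval + self.qrs_duration + self.t_end_time

    def scaled(self, amplitude: float = 1.0, width: float = 1.0) -> "BeatMorphology":
        """Copy with all amplitudes scaled by ``amplitude`` and all durations
        by ``width`` (used for ectopic beats)."""
        m = dataclasses.replace(self)
        for name in ("p_amplitude", "q_amplitude", "r_amplitude", "s_amplitude",
                     "st_offset", "t_amplitude"):
            setattr(m, name, getattr(m, name) * amplitude)
        for name in ("p_duration", "pr_interval", "qrs_duration",
                     "t_peak_time", "t_end_time"):
            setattr(m, name, getattr(m, name) * width)
        return m

    def true_params(self, rr_ms: float) -> dict[str, float]:
        """The 18 scalar ECG parameters this morphology encodes (continuous
        truth, before snapping to the sample grid)."""
        qt = self.qrs_duration + self.t_end_time
        jt = self.t_end_time
        out = {
            "RR": rr_ms,
            "PR": self.pr_interval,
            "P_D": self.p_duration,
            "QRS_D": self.qrs_duration,
            "Q_A": self.q_amplitude,
            "R_A": self.r_amplitude,
            "S_A": self.s_amplitude,
            "QRS_A": abs(self.q_amplitude) + abs(self.r_amplitude) + abs(self.s_amplitude),
            "ST_A": self.st_offset,
            "T_A": self.t_amplitude,
            "T_PE": self.t_end_time - self.t_peak_time,
            "QT": qt,
            "JT": jt,
        }
        qtc = correct_qt(qt / 1000.0, rr_ms / 1000.0)
        out.update({k: v * 1000.0 for k, v in qtc.items()})
        return out


@dataclass
class BeatFiducials:
    """Exact sample indices of the constructed landmarks of one beat."""

    p_onset: int
    p_peak: int
    p_end: int
    qrs_onset: int
    q_trough: int
    r_peak: int
    s_trough: int
    qrs_end: int
    t_peak: int
    t_end: int

    def shifted(self, k: int) -> "BeatFiducials":
        return BeatFiducials(**{f.name: getattr(self, f.name) + k
                                for f in dataclasses.fields(self)})

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def validate(self, n_samples: int | None = None) -> None:
        vals = list(self.as_dict().values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("fiducial indices must be strictly increasing")
        if n_samples is not None and (vals[0] < 0 or vals[-1] >= n_samples):
            raise ValueError("fiducial indices out of signal bounds")


@dataclass
class RecordingConfig:
    """Noise/rhythm settings for a multi-beat recording."""

    rr_mean: float = 365.0          # ms
    rr_sd: float = 10.0             # ms, beat-to-beat sinus variability
    n_beats: int = 40
    noise_sd: float = 0.01          # mV white noise
    baseline_wander_amplitude: float = 0.0   # mV
    baseline_wander_freq: float = 0.3        # Hz
    mains_amplitude: float = 0.0    # mV at 50 Hz
    mains_freq: float = 50.0
    ectopic_rate: float = 0.0       # probability per beat
    fs: float = 500.0
    seed: int = 0
    pad_ms: float = 400.0           # leading/trailing baseline

    def validate(self, morph: BeatMorphology) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ValueError("ectopic_rate must lie in [0, 1]")
        if self.rr_mean <= morph.duration:
            raise ValueError(
                f"rr_mean ({self.rr_mean} ms) must exceed the beat support "
                f"({morph.duration:.1f} ms)")


@dataclass
class RecordingTruth:
    """Ground truth for one generated recording (all indices global)."""

    fs: float
    onsets: np.ndarray            # beat start sample of each beat
    r_peaks: np.ndarray           # R-peak sample of each beat
    ectopic: np.ndarray           # bool per beat
    fiducials: list[BeatFiducials]
    rr_ms: np.ndarray             # realized RR intervals (len n_beats - 1)
    true_params: dict[str, float]  # continuous truth of the normal beat


# --------------------------------------------------------------------------
# single beat


def _snap(t_ms: float, fs: float) -> int:
    return int(round(t_ms * fs / 1000.0))


def make_beat(morph: BeatMorphology, fs: float) -> tuple[np.ndarray, BeatFiducials]:
    """Render one beat at sampling rate ``fs``.

    Returns the waveform (support exactly [P onset, T end], zero outside the
    constructed waves) and the exact sample indices of its landmarks.
    Raises ``ValueError`` on invalid morphology, non-positive ``fs``, or an
    ``fs`` too low to keep the landmark grid strictly ordered.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    morph.validate()

    p_on = 0
    p_end = _snap(morph.p_duration, fs)
    qrs_on = _snap(morph.pr_interval, fs)
    q_i = qrs_on + _snap(morph.q_frac * morph.qrs_duration, fs)
    r_i = qrs_on + _snap(morph.r_frac * morph.qrs_duration, fs)
    s_i = qrs_on + _snap(morph.s_frac * morph.qrs_duration, fs)
    qrs_end = qrs_on + _snap(morph.qrs_duration, fs)
    t_on = qrs_end + _snap(morph.t_rise_frac * morph.t_peak_time, fs)
    t_pk = qrs_end + _snap(morph.t_peak_time, fs)
    t_end = qrs_end + _snap(morph.t_end_time, fs)
    p_pk = int(round((p_on + p_end) / 2.0))

    fid = BeatFiducials(p_on, p_pk, p_end, qrs_on, q_i, r_i, s_i, qrs_end, t_pk, t_end)
    try:
        fid.validate()
    except ValueError as exc:
        raise ValueError(f"sampling rate {fs} Hz too low for this morphology") from exc

    wave = np.zeros(t_end + 1)

    # QRS + ST + T: piecewise linear through snapped corners
    bp_idx = np.array([qrs_on, q_i, r_i, s_i, qrs_end, t_on, t_pk, t_end], float)
    bp_val = np.array([0.0, morph.q_amplitude, morph.r_amplitude, morph.s_amplitude,
                       morph.st_offset, morph.st_offset, morph.t_amplitude, 0.0])
    xs = np.arange(qrs_on, t_end + 1)
    wave[qrs_on:t_end + 1] = np.interp(xs, bp_idx, bp_val)

    # P: truncated Gaussian, rescaled so the snapped endpoints are exactly 0
    if morph.p_amplitude != 0.0 and p_end > p_on:
        centre = (p_on + p_end) / 2.0
        sigma = (p_end - p_on) / 6.0
        i = np.arange(p_on, p_end + 1)
        g = np.exp(-0.5 * ((i - centre) / sigma) ** 2)
        edge = np.exp(-0.5 * ((p_end - centre) / sigma) ** 2)
        wave[p_on:p_end + 1] += morph.p_amplitude * (g - edge) / (1.0 - edge)

    return wave, fid


# --------------------------------------------------------------------------
# recording


def make_recording(morph: BeatMorphology,
                   cfg: RecordingConfig) -> tuple[np.ndarray, RecordingTruth]:
    """Generate a multi-beat single-lead recording with ground truth.

    Deterministic for a given ``cfg.seed``.  Noise components (white noise,
    baseline wander, 50 Hz mains) are additive and independently switchable
    through their amplitudes.  Ectopic beats are amplitude-scaled (x1.5) and
    widened (x1.6) copies of the normal beat, flagged in the truth.
    """
    cfg.validate(morph)
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    beat, fid = make_beat(morph, fs)
    ect_morph = morph.scaled(amplitude=1.5, width=1.6)
    ect_beat, ect_fid = make_beat(ect_morph, fs)

    min_rr = morph.duration + 20.0
    rr = rng.normal(cfg.rr_mean, cfg.rr_sd, size=cfg.n_beats - 1)
    rr = np.maximum(rr, min_rr)
    ectopic = rng.random(cfg.n_beats) < cfg.ectopic_rate

    pad = _snap(cfg.pad_ms, fs)
    onsets = pad + np.concatenate([[0], np.round(np.cumsum(rr) * fs / 1000.0)]).astype(int)
    n = onsets[-1] + max(len(beat), len(ect_beat)) + pad
    x = np.zeros(n)

    fiducials: list[BeatFiducials] = []
    r_peaks = np.empty(cfg.n_beats, dtype=int)
    for b, on in enumerate(onsets):
        w, f = (ect_beat, ect_fid) if ectopic[b] else (beat, fid)
        x[on:on + len(w)] += w
        fg = f.shifted(on)
        fiducials.append(fg)
        r_peaks[b] = fg.r_peak

    t = np.arange(n) / fs
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, size=n)
    if cfg.baseline_wander_amplitude > 0:
        x += cfg.baseline_wander_amplitude * np.sin(
            2 * np.pi * cfg.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi))
    if cfg.mains_amplitude > 0:
        x += cfg.mains_amplitude * np.sin(
            2 * np.pi * cfg.mains_freq * t + rng.uniform(0, 2 * np.pi))

    truth = RecordingTruth(fs=fs, onsets=onsets, r_peaks=r_peaks, ectopic=ectopic,
                           fiducials=fiducials, rr_ms=rr,
                           true_params=morph.true_params(cfg.rr_mean))
    return x, truth


def make_template(morph: BeatMorphology, fs: float = 500.0, noise_sd: float = 0.0,
                  pre_ms: float = 140.0, post_ms: float = 300.0,
                  rng: np.random.Generator | None = None):
    """One beat framed like an averaged template (baseline padding around R),
    with optional white noise at the *template* level.

    Returns ``(samples, r_index, BeatFiducials)`` with fiducials in the
    template frame.  Convenience wrapper used by the delineation stage tests.
    """
    wave, fid = make_beat(morph, fs)
    pre = _snap(pre_ms, fs)
    post = _snap(post_ms, fs)
    shift = pre - fid.r_peak
    if shift < 0:
        raise ValueError("pre_ms window too short for this morphology")
    samples = np.zeros(pre + post)
    end = min(len(samples), shift + len(wave))
    samples[shift:end] = wave[:end - shift]
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        samples = samples + rng.normal(0.0, noise_sd, size=len(samples))
    return samples, pre, fid.shifted(shift)


def random_morphology(rng: np.random.Generator) -> BeatMorphology:
    """Draw a beat geometry in the study's physiological ranges with every
    landmark geometrically well defined: the QRS terminal limb is steep
    enough for a slope criterion to localize its offset, and the T apex is
    clearly distinct from the ST level (shapes where e.g. T equals the ST
    pedestal have no meaningful landmark truth to compare against).
    """
    st = rng.uniform(-0.02, 0.08)
    t_amp = 0.0
    while abs(t_amp) < 0.08:        # a near-flat T apex has no landmark truth
        t_sign = -1.0 if rng.random() < 0.4 else 1.0
        t_amp = st + t_sign * rng.uniform(0.10, 0.25)
    t_peak = rng.uniform(60.0, 90.0)
    p_dur = rng.uniform(24.0, 34.0)
    return BeatMorphology(
        # edge slope of the Gaussian P scales with amplitude/duration; keep
        # it above the template noise floor so the onset/end are localizable
        p_amplitude=p_dur * rng.uniform(0.002, 0.0028),
        p_duration=p_dur,
        pr_interval=rng.uniform(64.0, 80.0),
        q_amplitude=-rng.uniform(0.10, 0.50),
        r_amplitude=rng.uniform(0.20, 0.50),
        s_amplitude=-rng.uniform(0.15, 0.40),
        qrs_duration=rng.uniform(38.0, 50.0),
        st_offset=st,
        t_amplitude=t_amp,
        t_peak_time=t_peak,
        t_end_time=t_peak + rng.uniform(40.0, 75.0))


# --------------------------------------------------------------------------
# study morphologies and reference values

_LEADS = ("I", "II", "III")

# Infarcted-group beat geometries per lead, seeded from the study's measured
# means (times: RR/PR/P_D/QRS_D/JT/T_PE; amplitudes: Q/R/S/ST/T; QT).
_MI_MORPH = {
    "I": dict(p_duration=29, pr_interval=71, qrs_duration=45,
              q_amplitude=-0.50, r_amplitude=0.21, s_amplitude=-0.12,
              st_offset=0.08, t_amplitude=0.10, t_end_time=137, t_peak_time=78),
    "II": dict(p_duration=32, pr_interval=76, qrs_duration=45,
               q_amplitude=-0.29, r_amplitude=0.22, s_amplitude=0.0,
               st_offset=0.01, t_amplitude=-0.03, t_end_time=161, t_peak_time=87),
    "III": dict(p_duration=24, pr_interval=72, qrs_duration=41,
                q_amplitude=-0.12, r_amplitude=0.37, s_amplitude=-0.02,
                st_offset=-0.02, t_amplitude=-0.05, t_end_time=127, t_peak_time=68),
}
_MI_RR = {"I": 365.0, "II": 397.0, "III": 394.0}

# Healthy-control beat geometries.  The study reports no control numbers, so
# these are a synthetic, documented fixture: textbook-plausible healthy rabbit
# limb-lead values (narrow Q, dominant R, no ST shift, upright rounded T).
_NORMAL_MORPH = {
    "I": dict(p_duration=28, pr_interval=70, qrs_duration=40,
              q_amplitude=-0.06, r_amplitude=0.38, s_amplitude=-0.06,
              st_offset=0.0, t_amplitude=0.12, t_end_time=120, t_peak_time=75),
    "II": dict(p_duration=30, pr_interval=72, qrs_duration=40,
               q_amplitude=-0.05, r_amplitude=0.45, s_amplitude=-0.08,
               st_offset=0.0, t_amplitude=0.15, t_end_time=125, t_peak_time=78),
    "III": dict(p_duration=26, pr_interval=70, qrs_duration=40,
                q_amplitude=-0.04, r_amplitude=0.30, s_amplitude=-0.05,
                st_offset=0.0, t_amplitude=0.10, t_end_time=118, t_peak_time=74),
}
_NORMAL_RR = {"I": 360.0, "II": 360.0, "III": 360.0}


def mi_morphology(lead: str = "I") -> BeatMorphology:
    """Infarcted-group beat morphology for one frontal lead."""
    return BeatMorphology(**_MI_MORPH[lead])


def normal_morphology(lead: str = "I") -> BeatMorphology:
    """Healthy-control beat morphology (synthetic reference fixture)."""
    return BeatMorphology(**_NORMAL_MORPH[lead])


def morphology_from_params(params: Mapping[str, float], lead: str = "I",
                           p_amplitude: float = 0.06) -> BeatMorphology:
    """Build a beat geometry from an 18-parameter set (inverse of
    ``BeatMorphology.true_params`` for the fields a parameter set pins down)."""
    jt = params["QT"] - params["QRS_D"]
    t_peak = jt - params["T_PE"]
    if t_peak <= 0:
        raise ValueError("QT - QRS_D must exceed T_PE")
    return BeatMorphology(
        p_amplitude=p_amplitude,
        p_duration=params["P_D"], pr_interval=params["PR"],
        q_amplitude=min(params["Q_A"], 0.0), r_amplitude=max(params["R_A"], 0.0),
        s_amplitude=min(params["S_A"], 0.0), qrs_duration=params["QRS_D"],
        st_offset=params["ST_A"], t_amplitude=params["T_A"],
        t_peak_time=t_peak, t_end_time=jt)


#: Per-lead healthy reference parameter sets (ECG_N), derived from the
#: control morphologies above.  A synthetic fixture, not a measured value.
NORMAL_REFERENCE: dict[str, dict[str, float]] = {
    lead: BeatMorphology(**_NORMAL_MORPH[lead]).true_params(_NORMAL_RR[lead])
    for lead in _LEADS
}


@dataclass
class AllometricStructure:
    """Generating law for one parameter's deviation from normality.

    ``log10|dev| = delta + beta * log10(VIMn) + Normal(0, residual_sd)``;
    the deviation added to the reference is ``direction * |dev|``.
    ``beta`` may be signed (as fitted tables print it); the regression slope
    of log-magnitude on log-VIMn recovers it as given.
    """

    lead: str
    beta: float
    delta: float
    residual_sd: float = 0.0
    direction: int = 1

    def validate(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


#: The study's fitted allometric coefficients (best lead per parameter):
#: (lead, beta, beta_se, delta, delta_se, r, p).  Deviation direction is
#: negative for parameters that shrink with infarct size (T_A, Q_A, PR).
STUDY_COEFFS: dict[str, dict] = {
    "QT":     dict(lead="III", beta=3.464, beta_se=1.072, delta=3.494, delta_se=0.8387, r=0.78, p=0.0145, direction=1),
    "T_A":    dict(lead="II", beta=-2.474, beta_se=0.7736, delta=-3.593, delta_se=0.5926, r=0.77, p=0.0151, direction=-1),
    "ST_A":   dict(lead="I", beta=1.832, beta_se=0.5997, delta=0.06115, delta_se=0.4994, r=0.75, p=0.0185, direction=1),
    "QT_FRA": dict(lead="I", beta=0.1042, beta_se=0.03840, delta=2.462, delta_se=0.03198, r=0.72, p=0.0300, direction=1),
    "T_PE":   dict(lead="III", beta=2.303, beta_se=0.9132, delta=3.087, delta_se=0.7142, r=0.69, p=0.0397, direction=1),
    "QT_FRI": dict(lead="I", beta=0.1691, beta_se=0.06926, delta=2.456, delta_se=0.05769, r=0.68, p=0.0447, direction=1),
    "QT_MA":  dict(lead="I", beta=0.1918, beta_se=0.07858, delta=2.346, delta_se=0.06545, r=0.68, p=0.0447, direction=1),
    "QT_B":   dict(lead="I", beta=0.1384, beta_se=0.0617, delta=2.531, delta_se=0.05142, r=0.64, p=0.0600, direction=1),
    "Q_A":    dict(lead="III", beta=-0.6352, beta_se=0.2849, delta=-0.8878, delta_se=0.2228, r=0.64, p=0.0610, direction=-1),
    "S_A":    dict(lead="III", beta=1.202, beta_se=0.6668, delta=0.03635, delta_se=0.5215, r=0.55, p=0.1145, direction=1),
    "P_D":    dict(lead="II", beta=1.011, beta_se=0.5893, delta=1.510, delta_se=0.4514, r=0.54, p=0.1299, direction=1),
    "QRS_A":  dict(lead="I", beta=1.210, beta_se=0.7190, delta=0.2376, delta_se=0.5988, r=0.53, p=0.1362, direction=1),
    "QRS_D":  dict(lead="III", beta=0.5699, beta_se=0.3995, delta=1.566, delta_se=0.3124, r=0.47, p=0.1968, direction=1),
    "RR":     dict(lead="I", beta=0.5025, beta_se=0.3669, delta=2.675, delta_se=0.3056, r=0.45, p=0.2131, direction=1),
    "PR":     dict(lead="II", beta=-0.7553, beta_se=0.7338, delta=0.3425, delta_se=0.5621, r=0.36, p=0.3376, direction=-1),
    "R_A":    dict(lead="I", beta=0.7621, beta_se=0.7972, delta=0.09869, delta_se=0.6639, r=0.34, p=0.3709, direction=1),
    "JT":     dict(lead="III", beta=0.5296, beta_se=0.6854, delta=1.821, delta_se=0.5360, r=0.26, p=0.4650, direction=1),
    "QT_HO":  dict(lead="III", beta=0.1448, beta_se=0.3730, delta=2.350, delta_se=0.2917, r=0.14, p=0.7095, direction=1),
}


def study_structures(params: list[str] | None = None,
                     residual_from_se: bool = False,
                     default_residual_sd: float = 0.0) -> dict[str, AllometricStructure]:
    """Turn ``STUDY_COEFFS`` rows into generating structures.

    ``residual_from_se=True`` leaves residual_sd at 0 here; per-cohort noise
    calibrated to the printed slope SE is handled by the caller (it depends
    on the realized log-VIMn spread; see ``residual_sd_for_se``).
    """
    names = list(STUDY_COEFFS) if params is None else params
    out = {}
    for name in names:
        c = STUDY_COEFFS[name]
        out[name] = AllometricStructure(lead=c["lead"], beta=c["beta"],
                                        delta=c["delta"],
                                        residual_sd=default_residual_sd,
                                        direction=c["direction"])
    return out


def residual_sd_for_se(log_vimn: np.ndarray, target_se: float) -> float:
    """Residual SD such that the OLS slope standard error on these x values
    equals ``target_se`` exactly:  SE(beta) = sigma / sqrt(Sxx)."""
    x = np.asarray(log_vimn, float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    return target_se * np.sqrt(sxx)


# --------------------------------------------------------------------------
# cohort


# beat-to-beat / animal-to-animal scatter of parameters that carry no
# allometric structure (healthy biological variability around the reference)
_NORMAL_SCATTER = {
    "RR": 20.0, "PR": 4.0, "P_D": 3.0, "QRS_D": 3.0, "JT": 8.0, "T_PE": 6.0,
    "QT": 8.0, "Q_A": 0.02, "R_A": 0.04, "S_A": 0.02, "ST_A": 0.01,
    "T_A": 0.02,
}

_DERIVED = {"QRS_A", "JT"} | set(QTC_NAMES)


@dataclass
class CohortConfig:
    """Study-cohort generator settings.

    Defaults mirror the study design: 10 infarcted + 5 healthy animals,
    planimetric infarct fractions spanning 7-35% of ventricular area,
    ventricular mass ~6 g of an ~8 g heart.
    """

    n_animals: int = 10              # infarcted
    n_controls: int = 5
    pim_range: tuple[float, float] = (0.07, 0.35)
    vm_mean: float = 6.0
    vm_sd: float = 0.6
    hw_mean: float = 8.0
    hw_sd: float = 0.8
    structures: dict[str, AllometricStructure] = field(default_factory=dict)
    normal_reference: dict[str, dict[str, float]] | None = None
    scatter_scale: float = 1.0       # multiplies _NORMAL_SCATTER
    #: optional per-parameter cap on |deviation| (physiological bound for
    #: cohorts that must render as actual beats); None = exact law
    dev_caps: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pim_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("pim_range must satisfy 0 < lo < hi < 1")
        if self.n_animals < 3:
            raise ValueError("n_animals must be >= 3 (fit impossible below)")
        for s in self.structures.values():
            s.validate()
        if self.vm_mean <= 0 or self.hw_mean <= 0:
            raise ValueError("masses must be positive")


def make_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic infarct cohort.

    Returns ``(params, planimetry)``:

    * ``params`` — one row per animal per lead with the 18 true ECG
      parameters plus ``animal_id``, ``lead``, ``group`` (MI/control);
    * ``planimetry`` — one row per animal: ``animal_id, PIM, VM_g, HW_g,
      VIMn`` (controls have PIM = VIMn = 0).

    Parameters named in ``cfg.structures`` follow the allometric law on the
    structure's lead; QTc's, QRS_A and JT without their own structure are
    derived from the generated QT/RR/amplitudes so the definitional
    identities hold; everything else scatters around the healthy reference.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.normal_reference if cfg.normal_reference is not None else NORMAL_REFERENCE

    lo, hi = cfg.pim_range
    n_mi = cfg.n_animals
    pim = rng.uniform(lo, hi, size=n_mi)
    vm = rng.normal(cfg.vm_mean, cfg.vm_sd, size=n_mi + cfg.n_controls)
    hw = rng.normal(cfg.hw_mean, cfg.hw_sd, size=n_mi + cfg.n_controls)
    for i in range(len(vm)):          # enforce 0 < VM <= HW
        while not (0 < vm[i] <= hw[i]):
            vm[i] = rng.normal(cfg.vm_mean, cfg.vm_sd)
            hw[i] = rng.normal(cfg.hw_mean, cfg.hw_sd)

    ids = [f"MI{i + 1:02d}" for i in range(n_mi)] + \
          [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    pim_all = np.concatenate([pim, np.zeros(cfg.n_controls)])
    vimn = pim_all * vm / hw

    plan = pd.DataFrame({"animal_id": ids, "PIM": pim_all,
                         "VM_g": vm, "HW_g": hw, "VIMn": vimn})

    rows = []
    base_params = [p for p in PARAM_NAMES if p not in _DERIVED]
    for a, aid in enumerate(ids):
        is_mi = a < n_mi
        for lead in _LEADS:
            row: dict = {"animal_id": aid, "lead": lead,
                         "group": "MI" if is_mi else "control"}
            for p in base_params:
                mu = ref[lead][p]
                sd = _NORMAL_SCATTER.get(p, 0.0) * cfg.scatter_scale
                val = mu + rng.normal(0.0, sd) if sd > 0 else mu
                st = cfg.structures.get(p)
                if is_mi and st is not None and st.lead == lead:
                    y = st.delta + st.beta * np.log10(vimn[a]) \
                        + rng.normal(0.0, st.residual_sd)
                    dev = 10.0 ** y
                    if cfg.dev_caps is not None and p in cfg.dev_caps:
                        dev = min(dev, cfg.dev_caps[p])
                    val = mu + st.direction * dev
                row[p] = val
            # derived parameters (unless given their own structure)
            row["QRS_A"] = abs(row["Q_A"]) + abs(row["R_A"]) + abs(row["S_A"])
            row["JT"] = row["QT"] - row["QRS_D"]
            if row["QT"] > 0 and row["RR"] > 1.0:
                qtc = correct_qt(row["QT"] / 1000.0, row["RR"] / 1000.0)
                for k, v in qtc.items():
                    row[k] = v * 1000.0
            else:       # extreme structured deviation: QTc undefined
                for k in QTC_NAMES:
                    row[k] = np.nan
            for p in _DERIVED:
                st = cfg.structures.get(p)
                if is_mi and st is not None and st.lead == lead:
                    y = st.delta + st.beta * np.log10(vimn[a]) \
                        + rng.normal(0.0, st.residual_sd)
                    dev = 10.0 ** y
                    if cfg.dev_caps is not None and p in cfg.dev_caps:
                        dev = min(dev, cfg.dev_caps[p])
                    row[p] = ref[lead][p] + st.direction * dev
            rows.append(row)

    params = pd.DataFrame(rows, columns=["animal_id", "lead", "group", *PARAM_NAMES])
    return params, plan
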