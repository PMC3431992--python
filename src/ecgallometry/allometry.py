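"""Allometric scaling of ECG deviations with normalized infarcted mass.

The model: an ECG parameter's deviation from its healthy reference scales
as a power law of the normalized ventricular infarcted mass,

    VIMn = PIM * VM / HW                  (dimensionless)
    |ECG_D - ECG_N| = alpha * VIMn**beta

which is linear in log-log coordinates,

    log10|ECG_D - ECG_N| = delta + beta * log10(VIMn),

with delta = log10(alpha).  ``allometric_fit`` estimates (beta, delta) by
ordinary least squares on the log10 scale and reports their standard
errors, the Pearson correlation r, and the two-sided p-value of the slope
(t distribution, n-2 df).  ``fit_all`` fits every parameter on every lead,
keeps the best lead per parameter by |r|, and ranks parameters by |r| —
the study's summary-table layout.

Base-10 logarithms throughout; the base only shifts delta, never beta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .measure import PARAM_NAMES

__all__ = [
    "PlanimetryRecord", "AllometricFit",
    "compute_vimn", "deviation", "allometric_fit", "fit_all",
    "normal_reference_from_params",
]


@dataclass
class PlanimetryRecord:
    """Necropsy/planimetry measurements of one animal."""

    animal_id: str
    pim: float      # infarcted fraction of total ventricular area (0-1)
    vm: float       # ventricular mass, g
    hw: float       # heart weight, g

    def validate(self) -> None:
        if not 0.0 <= self.pim <= 1.0:
            raise ValueError("PIM must lie in [0, 1] (fraction)")
        if self.hw <= 0:
            raise ValueError("heart weight must be positive")
        if self.vm <= 0 or self.vm > self.hw:
            raise ValueError("ventricular mass must satisfy 0 < VM <= HW")


@dataclass
class AllometricFit:
    """One log-log regression: a row of the ranked fit table.

    ``beta`` is the raw OLS slope of log10|deviation| on log10(VIMn) (so a
    zero-noise generator round-trips exactly); ``sign`` is the majority
    deviation direction and ``beta_signed = sign * |beta|`` is the reported
    slope carrying that direction.  ``beta_se``/``delta_se`` are standard
    errors of the regression coefficients.
    """

    parameter: str
    lead: str
    beta: float
    delta: float
    beta_se: float
    delta_se: float
    r: float
    p: float
    n: int
    sign: int = 1
    mode: str = "deviation"
    n_excluded: int = 0

    @property
    def beta_signed(self) -> float:
        return self.sign * abs(self.beta)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["beta_signed"] = self.beta_signed
        return d


def compute_vimn(pim: float, vm: float, hw: float,
                 pim_unit: str = "fraction") -> float:
    """Normalized ventricular infarcted mass VIMn = PIM * VM / HW.

    ``pim_unit`` is ``"fraction"`` (0-1, default) or ``"percent"`` (0-100).
    """
    if pim_unit == "percent":
        pim = pim / 100.0
    elif pim_unit != "fraction":
        raise ValueError("pim_unit must be 'fraction' or 'percent'")
    PlanimetryRecord("", pim, vm, hw).validate()
    return pim * vm / hw


def deviation(value_d: float, value_n: float) -> tuple[float, int, bool]:
    """Deviation from normality: (magnitude, sign, excluded).

    ``excluded`` marks a zero magnitude (log undefined, left out of the
    fit).  NaN inputs propagate as NaN magnitude with excluded=True.
    """
    if math.isnan(value_d) or math.isnan(value_n):
        return math.nan, 1, True
    diff = value_d - value_n
    if diff == 0.0:
        return 0.0, 1, True
    return abs(diff), (1 if diff > 0 else -1), False


def allometric_fit(vimn: np.ndarray, magnitudes: np.ndarray,
                   signs: np.ndarray | None = None,
                   parameter: str = "", lead: str = "",
                   mode: str = "deviation",
                   warn_mixed: bool = True) -> AllometricFit:
    """OLS fit of log10(magnitude) on log10(VIMn).

    Points with zero or NaN magnitude are excluded (counted in
    ``n_excluded``); any non-positive VIMn among the supplied points is an
    error; fewer than 3 usable pairs is an error.  Mixed deviation signs
    trigger a warning and the majority sign is reported.
    """
    vimn = np.asarray(vimn, float)
    magnitudes = np.asarray(magnitudes, float)
    if np.any(vimn <= 0):
        raise ValueError("all VIMn values must be strictly positive")
    usable = np.isfinite(magnitudes) & (magnitudes > 0)
    n_excluded = int(len(magnitudes) - usable.sum())
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable (VIMn, deviation) pairs")

    x = np.log10(vimn[usable])
    y = np.log10(magnitudes[usable])
    res = stats.linregress(x, y)

    if signs is None:
        sign = 1
    else:
        signs = np.asarray(signs)[usable]
        pos = int(np.sum(signs > 0))
        neg = int(np.sum(signs < 0))
        if pos and neg and warn_mixed:
            warnings.warn(
                f"mixed deviation signs for {parameter or 'parameter'} "
                f"({pos} positive, {neg} negative); majority sign reported")
        sign = 1 if pos >= neg else -1

    return AllometricFit(parameter=parameter, lead=lead,
                         beta=float(res.slope), delta=float(res.intercept),
                         beta_se=float(res.stderr),
                         delta_se=float(res.intercept_stderr),
                         r=float(res.rvalue), p=float(res.pvalue),
                         n=int(usable.sum()), sign=sign, mode=mode,
                         n_excluded=n_excluded)


def normal_reference_from_params(params: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-lead mean of the control group: the healthy reference ECG_N."""
    ctrl = params[params["group"] == "control"] if "group" in params.columns else params
    if ctrl.empty:
        raise ValueError("no control animals in the parameter table")
    cols = [c for c in PARAM_NAMES if c in ctrl.columns]
    return {lead: grp[cols].mean().to_dict()
            for lead, grp in ctrl.groupby("lead")}


def fit_all(params: pd.DataFrame, planimetry: pd.DataFrame,
            normal_ref: dict[str, dict[str, float]] | None = None,
            mode: str = "deviation", pim_unit: str = "fraction",
            alpha: float = 0.05) -> pd.DataFrame:
    """Fit every parameter on every lead and rank by goodness of fit.

    ``params`` holds one row per animal/lead with parameter columns (the
    infarcted animals are ``group == "MI"`` when a group column exists);
    ``planimetry`` holds ``animal_id, PIM, VM_g, HW_g``.  In ``deviation``
    mode each diseased value is referenced to ``normal_ref`` (computed from
    the control rows when not supplied); ``direct`` mode regresses
    log10|value| itself.

    Returns a DataFrame with one row per parameter (the lead with the best
    |r|), sorted by |r| descending, including the all-leads fits' columns
    beta, beta_signed, delta, their SEs, r, p, n and a significance flag at
    ``alpha``.  Parameters with fewer than 3 usable animals in every lead
    come back with ``fittable = False``.
    """
    if mode not in ("deviation", "direct"):
        raise ValueError("mode must be 'deviation' or 'direct'")
    mi = params[params["group"] == "MI"] if "group" in params.columns else params
    if normal_ref is None and mode == "deviation":
        normal_ref = normal_reference_from_params(params)

    plan = planimetry.copy()
    plan["VIMn"] = [compute_vimn(p, v, h, pim_unit=pim_unit)
                    for p, v, h in zip(plan["PIM"], plan["VM_g"], plan["HW_g"])]
    merged = mi.merge(plan[["animal_id", "VIMn"]], on="animal_id", how="inner")
    merged = merged[merged["VIMn"] > 0]

    rows = []
    param_cols = [c for c in PARAM_NAMES if c in merged.columns]
    for p in param_cols:
        best: AllometricFit | None = None
        for lead, grp in merged.groupby("lead"):
            vals = grp[p].to_numpy(float)
            vimn = grp["VIMn"].to_numpy(float)
            if mode == "deviation":
                ref = normal_ref[lead][p]
                devs = [deviation(v, ref) for v in vals]
                mags = np.array([d[0] for d in devs])
                signs = np.array([d[1] for d in devs])
            else:
                mags = np.abs(vals)
                signs = np.sign(vals).astype(int)
                signs[signs == 0] = 1
            try:
                # mixed signs are expected in bulk (structureless
                # parameters scatter around the reference); recorded in the
                # mixed_sign column rather than warned per fit
                fit = allometric_fit(vimn, mags, signs, parameter=p,
                                     lead=lead, mode=mode, warn_mixed=False)
            except ValueError:
                continue
            fit_mixed = bool(np.any(signs > 0) and np.any(signs < 0))
            if best is None or abs(fit.r) > abs(best.r):
                best = fit
                best_mixed = fit_mixed
        if best is None:
            rows.append({"parameter": p, "fittable": False})
        else:
            d = best.as_dict()
            d["fittable"] = True
            d["significant"] = bool(best.p < alpha)
            d["mixed_sign"] = best_mixed
            rows.append(d)

    table = pd.DataFrame(rows)
    order = table["r"].abs().fillna(-1.0)
    table = table.loc[order.sort_values(ascending=False).index].reset_index(drop=True)
    return table
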