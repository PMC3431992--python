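"""ECG parameter assembly and group statistics.

Builds the 18 scalar parameters of one animal/lead from a delineated beat
template (intervals in ms, amplitudes in mV relative to the isoelectric
level), applies the five heart-rate QT corrections, and produces the
per-lead summary tables and lead-comparison statistics.

QT correction formulas (QT and RR in seconds, HR = 60/RR in bpm):

    Bazett       QT_B   = QT / RR**(1/2)
    Framingham   QT_FRA = QT + 0.154 * (1 - RR)
    Fridericia   QT_FRI = QT / RR**(1/3)
    Hodge        QT_HO  = QT + 0.00175 * (HR - 60)
    Matsunaga    QT_MA  = QT * log(600) / log(1000 * RR)

All five coincide with QT at the 60 bpm normalization point (RR = 1 s) for
the first four and at RR = 0.6 s for Matsunaga, and each is strictly
increasing in QT at fixed RR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .delineate import apex_amplitude, st_amplitude

__all__ = [
    "PARAM_NAMES", "QTC_NAMES", "TIME_PARAMS", "AMPLITUDE_PARAMS",
    "correct_qt", "extract_params", "summarize_by_lead", "compare_leads",
    "LeadComparison",
]

QTC_NAMES = ("QT_B", "QT_FRA", "QT_FRI", "QT_HO", "QT_MA")

#: canonical order of the 18 reported parameters (summary-table column order)
PARAM_NAMES = (
    "RR", "PR", "P_D", "QRS_D", "JT", "T_PE",          # time-related
    "Q_A", "R_A", "S_A", "QRS_A", "ST_A", "T_A",       # amplitude-related
    "QT", *QTC_NAMES,                                   # QT family
)

TIME_PARAMS = ("RR", "PR", "P_D", "QRS_D", "JT", "T_PE", "QT", *QTC_NAMES)
AMPLITUDE_PARAMS = ("Q_A", "R_A", "S_A", "QRS_A", "ST_A", "T_A")


def correct_qt(qt: float, rr: float) -> dict[str, float]:
    """Five heart-rate-corrected QT values, in seconds.

    ``qt`` and ``rr`` are in seconds.  Raises ``ValueError`` on non-positive
    inputs or when the Matsunaga logarithm is undefined (1000*RR <= 1).
    """
    if qt <= 0 or rr <= 0:
        raise ValueError("qt and rr must be strictly positive (seconds)")
    if 1000.0 * rr <= 1.0:
        raise ValueError("Matsunaga correction undefined for 1000*RR <= 1")
    hr = 60.0 / rr
    return {
        "QT_B": qt / math.sqrt(rr),
        "QT_FRA": qt + 0.154 * (1.0 - rr),
        "QT_FRI": qt / rr ** (1.0 / 3.0),
        "QT_HO": qt + 0.00175 * (hr - 60.0),
        "QT_MA": qt * math.log(600.0) / math.log(1000.0 * rr),
    }


def extract_params(fids, tpl, rr_ms: float) -> dict[str, float]:
    """Assemble the 18 scalar ECG parameters from a delineated template.

    ``fids`` is a ``FiducialSet`` (indices within the template, isoelectric
    level in mV), ``tpl`` a ``BeatTemplate``.  Missing fiducials propagate
    as NaN in the parameters that need them; all others are still produced.
    """
    if rr_ms <= 0:
        raise ValueError("rr must be strictly positive")
    x = np.asarray(tpl.samples, float)
    dt = 1000.0 / tpl.fs
    iso = fids.isoelectric_level

    def ms(a, b):
        if a is None or b is None:
            return math.nan
        return (b - a) * dt

    def amp(i):
        if i is None:
            return math.nan
        return x[i] - iso

    out: dict[str, float] = {"RR": rr_ms}
    out["PR"] = ms(fids.p_onset, fids.qrs_onset)
    out["P_D"] = ms(fids.p_onset, fids.p_end)
    out["QRS_D"] = ms(fids.qrs_onset, fids.qrs_end)
    out["QT"] = ms(fids.qrs_onset, fids.t_end)
    out["JT"] = out["QT"] - out["QRS_D"]
    out["T_PE"] = ms(fids.t_peak, fids.t_end)
    # absent Q/S waves are reported as 0 amplitude (trough index None but
    # wave searched) -- the delineator sets troughs to None only when absent
    out["Q_A"] = amp(fids.q_trough) if fids.q_trough is not None else 0.0
    out["R_A"] = amp(fids.r_peak)
    out["S_A"] = amp(fids.s_trough) if fids.s_trough is not None else 0.0
    out["QRS_A"] = (abs(out["Q_A"]) + abs(out["R_A"]) + abs(out["S_A"])
                    if not math.isnan(out["R_A"]) else math.nan)
    st_i = getattr(fids, "st_point", None)
    out["ST_A"] = st_amplitude(x, st_i, iso) if st_i is not None else math.nan
    out["T_A"] = (apex_amplitude(x, fids.t_peak, iso)[1]
                  if fids.t_peak is not None else math.nan)
    if math.isnan(out["QT"]):
        for k in QTC_NAMES:
            out[k] = math.nan
    else:
        qtc = correct_qt(out["QT"] / 1000.0, rr_ms / 1000.0)
        out.update({k: v * 1000.0 for k, v in qtc.items()})
    return {k: out[k] for k in ("RR",) + tuple(p for p in PARAM_NAMES if p != "RR")}


def summarize_by_lead(params: pd.DataFrame,
                      value_cols: tuple[str, ...] = PARAM_NAMES) -> pd.DataFrame:
    """Mean +/- SD of each parameter per lead (sample SD, n-1 denominator).

    ``params`` has one row per animal/lead.  Leads with a single animal get
    NaN SD.  Raises on leads with no rows at all.
    """
    cols = [c for c in value_cols if c in params.columns]
    if params.groupby("lead").size().min() < 1:
        raise ValueError("every lead needs at least one animal")
    g = params.groupby("lead")[cols]
    out = g.agg(["mean", "std", "count"])
    out.columns = [f"{p}_{s}" for p, s in out.columns]
    return out


@dataclass
class LeadComparison:
    """Result of comparing one parameter across the three frontal leads."""

    parameter: str
    test_used: str                       # "anova_bonferroni" | "kruskal_dunn"
    overall_p: float
    normality_p: dict[str, float]
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)
    alpha: float = 0.05


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc z tests on pooled ranks, tie-corrected, with a
    Bonferroni adjustment over the pairwise contrasts."""
    leads = list(samples)
    pooled = np.concatenate([samples[k] for k in leads])
    ranks = stats.rankdata(pooled)
    n_tot = len(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts ** 3 - counts)
    var_term = n_tot * (n_tot + 1) / 12.0 - ties / (12.0 * (n_tot - 1))

    mean_rank, sizes, i = {}, {}, 0
    for k in leads:
        n_k = len(samples[k])
        mean_rank[k] = ranks[i:i + n_k].mean()
        sizes[k] = n_k
        i += n_k

    m = len(leads) * (len(leads) - 1) // 2
    out = {}
    for a, b in itertools.combinations(leads, 2):
        se = math.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * m)
    return out


def compare_leads(samples: dict[str, np.ndarray], parameter: str = "",
                  alpha: float = 0.05) -> LeadComparison:
    """Compare one parameter among leads.

    Each lead's values are tested for normality (D'Agostino & Pearson); if
    every lead passes at ``alpha``, a one-way ANOVA with Bonferroni-adjusted
    pairwise t tests is used, otherwise Kruskal-Wallis with Dunn's post-hoc
    test.  Requires >= 3 leads and >= 3 values per lead.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 leads to compare")
    clean = {k: np.asarray(v, float)[~np.isnan(np.asarray(v, float))]
             for k, v in samples.items()}
    if min(len(v) for v in clean.values()) < 3:
        raise ValueError("need at least 3 values per lead")

    normality = {}
    for k, v in clean.items():
        if np.ptp(v) == 0 or len(v) < 8:
            normality[k] = 0.0        # unassessable, route to nonparametric
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                p = float(stats.normaltest(v).pvalue)
            except ValueError:        # too few samples for the test
                p = math.nan
        normality[k] = 0.0 if math.isnan(p) else p

    groups = list(clean.values())
    if all(p > alpha for p in normality.values()):
        test = "anova_bonferroni"
        if all(np.ptp(g) == 0 for g in groups) and \
                len({g[0] for g in groups}) == 1:
            overall = 1.0
            pairwise = {pair: 1.0 for pair in
                        itertools.combinations(clean, 2)}
        else:
            overall = float(stats.f_oneway(*groups).pvalue)
            m = len(groups) * (len(groups) - 1) // 2
            pairwise = {}
            for a, b in itertools.combinations(clean, 2):
                p = float(stats.ttest_ind(clean[a], clean[b]).pvalue)
                pairwise[(a, b)] = min(1.0, p * m)
    else:
        test = "kruskal_dunn"
        try:
            overall = float(stats.kruskal(*groups).pvalue)
        except ValueError:            # all values identical across groups
            overall = 1.0
        pairwise = _dunn_pairwise(clean)

    sig = {k: bool(p < alpha) for k, p in pairwise.items()}
    return LeadComparison(parameter=parameter, test_used=test, overall_p=overall,
                          normality_p=normality, pairwise_p=pairwise,
                          significant=sig, alpha=alpha)


def compare_all_leads(params: pd.DataFrame, alpha: float = 0.05,
                      value_cols: tuple[str, ...] = PARAM_NAMES) -> list[LeadComparison]:
    """Run ``compare_leads`` for every parameter column in a cohort table."""
    out = []
    for p in value_cols:
        if p not in params.columns:
            continue
        samples = {lead: grp[p].to_numpy()
                   for lead, grp in params.groupby("lead")}
        out.append(compare_leads(samples, parameter=p, alpha=alpha))
    return out
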