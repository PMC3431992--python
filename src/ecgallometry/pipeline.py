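"""End-to-end orchestration: synthesize (or load) -> preprocess ->
delineate -> measure -> allometric fit, with config validation, run
logging and TSV/JSON report output.

The analysis scripts under ``analysis/`` are thin drivers over the stage
functions here; every stage is also individually re-runnable from its
serialized intermediates (see ``io``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as eio
from .allometry import fit_all, normal_reference_from_params
from .delineate import DelineationError, delineate_template
from .measure import PARAM_NAMES, compare_all_leads, extract_params, summarize_by_lead
from .preprocess import (ECGSignal, InsufficientBeatsError, build_template,
                         correct_baseline, detect_qrs, remove_mains)
from .synth import (CohortConfig, RecordingConfig, make_cohort, make_recording,
                    morphology_from_params, residual_sd_for_se, study_structures,
                    NORMAL_REFERENCE, STUDY_COEFFS)

__all__ = ["DEFAULT_CONFIG", "ConfigError", "load_config", "validate_config",
           "run_pipeline", "slope_recovery_study"]

log = logging.getLogger("ecgallometry")

#: Expected sqrt(Sxx) of log10(VIMn) for the default cohort design
#: (PIM ~ U(0.07, 0.35), VM/HW = 0.75, n = 10); used only to translate the
#: study's printed slope SEs into demo residual SDs.
_SQRT_SXX_DESIGN = 0.67

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "synthetic",            # "synthetic" | "files"
    "seed": 42,
    "cohort": {
        "n_animals": 10, "n_controls": 5,
        "pim_range": (0.07, 0.35),
        "vm_mean": 6.0, "vm_sd": 0.6, "hw_mean": 8.0, "hw_sd": 0.8,
        "residual_scale": 1.0,      # multiplies the SE-matched residual SDs
        "structures": "study",      # "study" | "none" | dict
    },
    "recording": {
        "n_beats": 40, "rr_sd": 10.0, "noise_sd": 0.01,
        "baseline_wander_amplitude": 0.10, "mains_amplitude": 0.02,
        "ectopic_rate": 0.01, "fs": 500.0,
    },
    "template": {"pre_ms": 140.0, "post_ms": 300.0, "corr_threshold": 0.98},
    "fit": {"mode": "deviation", "pim_unit": "fraction", "alpha": 0.05},
    "paths": {},                    # files mode: recordings_dir, planimetry
}


#: physiological caps on |deviation| (ms / mV) so every synthetic-cohort row
#: renders as an actual beat train: the log-normal residual has an unbounded
#: upper tail, but a rabbit QT cannot lengthen by 300 ms
_DEMO_DEV_CAPS: dict[str, float] = {
    "RR": 120.0, "PR": 25.0, "P_D": 12.0, "QRS_D": 25.0, "JT": 60.0,
    "T_PE": 40.0, "QT": 80.0, "QT_B": 80.0, "QT_FRA": 80.0, "QT_FRI": 80.0,
    "QT_HO": 80.0, "QT_MA": 80.0,
    "Q_A": 0.6, "R_A": 0.6, "S_A": 0.6, "QRS_A": 0.9, "ST_A": 0.25, "T_A": 0.5,
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def load_config(path: str | Path) -> dict:
    """Read a run configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict | None) -> tuple[dict, list[str]]:
    """Fill defaults, normalize units and collect contradictions.

    Returns ``(normalized_config, warnings)``; hard errors are aggregated
    into a single ``ConfigError`` naming the offending fields.
    """
    cfg = _merge(DEFAULT_CONFIG, cfg or {})
    errors: list[str] = []
    warns: list[str] = []

    if cfg["mode"] not in ("synthetic", "files"):
        errors.append(f"mode: unknown value {cfg['mode']!r}")
    if cfg["mode"] == "synthetic" and not isinstance(cfg.get("seed"), int):
        errors.append("seed: synthetic mode requires an integer seed")
    rec = cfg["recording"]
    if rec["fs"] <= 0:
        errors.append("recording.fs: must be positive")
    if not 0 <= rec["ectopic_rate"] <= 1:
        errors.append("recording.ectopic_rate: must lie in [0, 1]")
    lo, hi = cfg["cohort"]["pim_range"]
    if not 0 < lo < hi < 1:
        errors.append("cohort.pim_range: must satisfy 0 < lo < hi < 1")
    if cfg["cohort"]["n_animals"] < 3:
        errors.append("cohort.n_animals: need >= 3 for any fit")
    if cfg["fit"]["mode"] not in ("deviation", "direct"):
        errors.append("fit.mode: must be 'deviation' or 'direct'")
    if cfg["fit"]["pim_unit"] not in ("fraction", "percent"):
        errors.append("fit.pim_unit: must be 'fraction' or 'percent'")

    if cfg["mode"] == "files":
        paths = cfg["paths"]
        for key in ("recordings_dir", "planimetry"):
            if key not in paths:
                errors.append(f"paths.{key}: required in files mode")
            elif not Path(paths[key]).exists():
                errors.append(f"paths.{key}: {paths[key]} does not exist")
        plan_path = paths.get("planimetry")
        if plan_path and Path(plan_path).exists():
            plan = pd.read_csv(plan_path, sep="\t")
            if "PIM" in plan:
                pim = plan["PIM"].to_numpy(float)
                if cfg["fit"]["pim_unit"] == "percent" and np.nanmax(pim) <= 1.0:
                    warns.append("paths.planimetry: PIM declared percent but all "
                                 "values <= 1 — unit suspicion")
                if cfg["fit"]["pim_unit"] == "fraction" and np.nanmax(pim) > 1.0:
                    warns.append("paths.planimetry: PIM declared fraction but "
                                 "values > 1 — unit suspicion")

    if errors:
        raise ConfigError(errors)
    return cfg, warns


# --------------------------------------------------------------------------
# stages


def simulate_cohort(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 1: synthetic cohort (true parameters + planimetry)."""
    c = cfg["cohort"]
    structures = c["structures"]
    if structures == "study":
        structures = study_structures()
        for name, st in structures.items():
            st.residual_sd = (STUDY_COEFFS[name]["beta_se"] * _SQRT_SXX_DESIGN
                              * c["residual_scale"])
    elif structures == "none":
        structures = {}
    caps = {p: _DEMO_DEV_CAPS[p] for p in structures if p in _DEMO_DEV_CAPS}
    cohort_cfg = CohortConfig(
        n_animals=c["n_animals"], n_controls=c["n_controls"],
        pim_range=tuple(c["pim_range"]), vm_mean=c["vm_mean"], vm_sd=c["vm_sd"],
        hw_mean=c["hw_mean"], hw_sd=c["hw_sd"], structures=structures,
        dev_caps=caps, seed=cfg["seed"])
    return make_cohort(cohort_cfg)


def preprocess_recording(sig: ECGSignal, tpl_cfg: dict):
    """Stage 2 for one recording: mains removal, detection, baseline
    correction, signal averaging.  Returns (template, rr_ms)."""
    sig = remove_mains(sig)
    r = detect_qrs(sig)
    if len(r) < 3:
        raise InsufficientBeatsError("too few QRS detections")
    sig = correct_baseline(sig, r)
    rr_ms = float(np.median(np.diff(r))) * 1000.0 / sig.fs
    tpl = build_template(sig, r, pre_ms=tpl_cfg["pre_ms"],
                         post_ms=tpl_cfg["post_ms"],
                         corr_threshold=tpl_cfg["corr_threshold"])
    return tpl, rr_ms


def measure_cohort(cohort: pd.DataFrame, cfg: dict) -> tuple[pd.DataFrame, dict]:
    """Stages 2-4 over every animal/lead: synthesize the recording from the
    true parameters, preprocess, delineate and measure.

    Returns the measured parameter table (NaN where a wave was absent) and
    a dict of templates/fiducials for reporting.  Animal/leads whose
    template fails the averaging budget are skipped with a log entry.
    """
    rec = cfg["recording"]
    artifacts: dict[str, Any] = {}
    rows = []
    for i, row in cohort.reset_index(drop=True).iterrows():
        try:
            morph = morphology_from_params(row, lead=row["lead"])
        except ValueError as exc:
            log.warning("skip %s/%s: unbuildable morphology (%s)",
                        row["animal_id"], row["lead"], exc)
            continue
        rcfg = RecordingConfig(
            rr_mean=float(row["RR"]), rr_sd=rec["rr_sd"],
            n_beats=rec["n_beats"], noise_sd=rec["noise_sd"],
            baseline_wander_amplitude=rec["baseline_wander_amplitude"],
            mains_amplitude=rec["mains_amplitude"],
            ectopic_rate=rec["ectopic_rate"], fs=rec["fs"],
            seed=int(cfg["seed"]) * 100003 % (2 ** 31) + i)
        try:
            samples, _truth = make_recording(morph, rcfg)
            sig = ECGSignal(samples, fs=rec["fs"], lead=row["lead"])
            tpl, rr_ms = preprocess_recording(sig, cfg["template"])
            fids = delineate_template(tpl)
            params = extract_params(fids, tpl, rr_ms)
        except (InsufficientBeatsError, DelineationError, ValueError) as exc:
            log.warning("skip %s/%s: %s", row["animal_id"], row["lead"], exc)
            continue
        out = {"animal_id": row["animal_id"], "lead": row["lead"],
               "group": row["group"], **params}
        rows.append(out)
        artifacts[f"{row['animal_id']}_{row['lead']}"] = (tpl, fids)
    measured = pd.DataFrame(rows, columns=["animal_id", "lead", "group", *PARAM_NAMES])
    return measured, artifacts


def load_recordings(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Files mode: measured parameters from recording CSVs named
    ``<animal>_<lead>.csv`` plus the planimetry TSV."""
    paths = cfg["paths"]
    plan = pd.read_csv(paths["planimetry"], sep="\t")
    rows = []
    for f in sorted(Path(paths["recordings_dir"]).glob("*.csv")):
        animal, _, lead = f.stem.rpartition("_")
        sig = eio.read_signal_csv(f, lead=lead)
        try:
            tpl, rr_ms = preprocess_recording(sig, cfg["template"])
            fids = delineate_template(tpl)
            params = extract_params(fids, tpl, rr_ms)
        except (InsufficientBeatsError, DelineationError) as exc:
            raise RuntimeError(f"preprocess stage failed on {f.name}: {exc}") from exc
        group = "control" if animal.upper().startswith("C") else "MI"
        rows.append({"animal_id": animal, "lead": lead, "group": group, **params})
    measured = pd.DataFrame(rows, columns=["animal_id", "lead", "group", *PARAM_NAMES])
    return measured, plan


def run_pipeline(cfg: dict | None = None, outdir: str | Path = "results") -> dict:
    """Run the whole analysis and write the report bundle.

    Outputs under ``outdir``: the cohort truth (synthetic mode), measured
    parameter table, per-lead summary tables (time/amplitude/QT), the
    lead-comparison statistics, the ranked allometric fit table, per-animal
    fiducial JSONs, and a run log with the seed and all thresholds.
    Deterministic (bit-identical TSVs) for a fixed config in synthetic mode.
    """
    cfg, warns = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w in warns:
        log.warning("%s", w)

    bundle: dict[str, Any] = {"config": cfg, "warnings": warns}
    if cfg["mode"] == "synthetic":
        cohort, plan = simulate_cohort(cfg)
        eio.write_table(cohort, outdir / "cohort_true_params.tsv")
        measured, artifacts = measure_cohort(cohort, cfg)
    else:
        measured, plan = load_recordings(cfg)
        artifacts = {}
    eio.write_table(plan, outdir / "planimetry.tsv")
    eio.write_table(measured, outdir / "measured_params.tsv")

    mi = measured[measured["group"] == "MI"]
    summary = summarize_by_lead(mi)
    eio.write_table(summary.reset_index(), outdir / "summary_by_lead.tsv")
    comparisons = compare_all_leads(mi.dropna(axis=1, how="any"))
    comp_rows = [{"parameter": c.parameter, "test": c.test_used,
                  "overall_p": c.overall_p,
                  **{f"p_{a}_vs_{b}": p for (a, b), p in c.pairwise_p.items()}}
                 for c in comparisons]
    eio.write_table(pd.DataFrame(comp_rows), outdir / "lead_comparisons.tsv")

    normal_ref = (normal_reference_from_params(measured)
                  if (measured["group"] == "control").any() else NORMAL_REFERENCE)
    fits = fit_all(measured, plan, normal_ref=normal_ref,
                   mode=cfg["fit"]["mode"], pim_unit=cfg["fit"]["pim_unit"],
                   alpha=cfg["fit"]["alpha"])
    eio.write_table(fits, outdir / "allometric_fits.tsv")

    fid_dir = outdir / "fiducials"
    fid_dir.mkdir(exist_ok=True)
    for key, (tpl, fids) in artifacts.items():
        eio.write_fiducials_json(fids, tpl.fs, fid_dir / f"{key}.json")

    run_log = {"seed": cfg.get("seed"), "config": _jsonable(cfg),
               "python": platform.python_version(),
               "numpy": np.__version__, "pandas": pd.__version__}
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))

    bundle.update(measured=measured, planimetry=plan, summary=summary,
                  comparisons=comparisons, fits=fits, outdir=outdir)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# slope-recovery study (parameter recovery against the printed coefficients)


def slope_recovery_study(parameter: str, n_reps: int = 500, n_animals: int = 9,
                         seed: int = 0) -> dict[str, float]:
    """Mean recovered log-log slope for one parameter over ``n_reps``
    synthetic cohorts of ``n_animals``.

    Each cohort is generated by the cohort module under the study's printed
    coefficients for that parameter (its best lead), with VM/HW fixed and
    the residual SD calibrated per cohort so the OLS slope standard error
    matches the printed one; each cohort is then fitted in deviation mode
    and the signed slope recorded.
    """
    from .allometry import allometric_fit, deviation
    coef = STUDY_COEFFS[parameter]
    lead = coef["lead"]
    ref = NORMAL_REFERENCE[lead][parameter]
    rng = np.random.default_rng(seed)
    betas = np.empty(n_reps)
    for rep in range(n_reps):
        s = int(rng.integers(0, 2 ** 31 - 1))
        base = CohortConfig(n_animals=n_animals, n_controls=0,
                            vm_sd=0.0, hw_sd=0.0,
                            structures=study_structures([parameter]), seed=s)
        _, plan = make_cohort(base)      # planimetry draw (zero residual)
        x = np.log10(plan.loc[plan["VIMn"] > 0, "VIMn"].to_numpy())
        sigma = residual_sd_for_se(x, coef["beta_se"])
        structures = study_structures([parameter])
        structures[parameter].residual_sd = sigma
        cfg = dataclasses.replace(base, structures=structures)
        cohort, plan = make_cohort(cfg)  # same seed -> same planimetry
        grp = cohort[cohort["lead"] == lead].merge(
            plan[["animal_id", "VIMn"]], on="animal_id")
        devs = [deviation(v, ref) for v in grp[parameter]]
        fit = allometric_fit(grp["VIMn"].to_numpy(),
                             np.array([d[0] for d in devs]),
                             np.array([d[1] for d in devs]),
                             parameter=parameter, lead=lead)
        betas[rep] = fit.beta_signed
    return {"parameter": parameter, "lead": lead,
            "mean_beta": float(np.mean(betas)), "sd_beta": float(np.std(betas)),
            "generating_beta": coef["beta"], "n_reps": n_reps, "n": n_animals}
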