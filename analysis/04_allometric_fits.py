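#!/usr/bin/env python
"""Fit the allometric law log10|ECG_D - ECG_N| = delta + beta*log10(VIMn)
for every parameter on every lead and rank parameters by goodness of fit.

Two fits are reported: on the cohort's true parameters (what the
generating coefficients imply at this sample size) and on the parameters
measured from the synthetic recordings (what survives template averaging
and delineation).  The healthy reference ECG_N is the per-lead mean of the
measured control animals for the measured fit, and the generator's
reference for the true fit.
"""

import argparse
from pathlib import Path

import pandas as pd

from ecgallometry.allometry import fit_all, normal_reference_from_params
from ecgallometry.io import write_table
from ecgallometry.synth import NORMAL_REFERENCE

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

plan = pd.read_csv(args.outdir / "planimetry.tsv", sep="\t")
cohort = pd.read_csv(args.outdir / "cohort_true_params.tsv", sep="\t")
measured = pd.read_csv(args.outdir / "measured_params.tsv", sep="\t")

cols = ["parameter", "lead", "beta_signed", "beta_se", "delta", "delta_se",
        "r", "p", "n", "significant"]

fits_true = fit_all(cohort, plan, normal_ref=NORMAL_REFERENCE)
write_table(fits_true, args.outdir / "allometric_fits_true.tsv")
print("fits on the true cohort parameters (top 8 by |r|):")
print(fits_true[fits_true["fittable"]][cols].head(8).round(4).to_string(index=False))
n_sig = int(fits_true["significant"].fillna(False).sum())
print(f"  {n_sig} of 18 parameters scale significantly with VIMn (p < 0.05)")

ref = normal_reference_from_params(measured)
fits_meas = fit_all(measured, plan, normal_ref=ref)
write_table(fits_meas, args.outdir / "allometric_fits_measured.tsv")
print("\nfits on the parameters measured from the synthetic recordings:")
print(fits_meas[fits_meas["fittable"]][cols].head(8).round(4).to_string(index=False))
print(
    "\nNote: the generating coefficients imply deviations that are often\n"
    "below the delineation resolution (sub-millisecond interval shifts at\n"
    "small infarcts), so the measured-parameter fits are noise-limited —\n"
    "see docs/methods.md for the analysis of this floor.")
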