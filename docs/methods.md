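# Methods

This note documents the models implemented in `ecgallometry`, the choices
made where the underlying methods leave constants open, the conditions the
synthetic-data generator emulates, and the known limitations.  Units are
milliseconds, millivolts and Hz throughout; logarithms are base 10.

## 1. Synthetic beat model (`synth`)

A beat is a deterministic geometric object so that every landmark has an
*exact* truth to validate against:

* **P wave** — a Gaussian bump (σ = duration/6) truncated at ±3σ and
  rescaled so the snapped endpoints are exactly zero.
* **QRS** — piecewise linear through the Q trough (at 20 % of the QRS
  duration), R peak (45 %) and S trough (70 %), starting at 0 at QRS onset
  and ending at the ST level at QRS offset.  Q ≤ 0 ≤ R and S ≤ 0 by type.
* **ST segment** — constant at `st_offset` until the T upstroke begins
  (halfway to the T peak).
* **T wave** — piecewise linear: rise from the ST level to `t_amplitude`
  at `t_peak_time` after QRS offset, then a *straight* descent to zero at
  `t_end_time`.  The linear tail makes the tangent-intersection T-end rule
  exactly well defined (a curved tail has no unambiguous "end", so there
  would be no truth to test against), and the corner apex gives an
  unambiguous T-peak truth.

All landmark times are snapped to the sample grid before rendering, so the
returned fiducial indices are exact sample positions of the constructed
corners.  The continuous parameter truths (e.g. T_PE = `t_end_time` −
`t_peak_time`) are kept alongside, independent of sampling rate.

Default morphologies: the infarct-group beat geometries per lead are
seeded from the study's measured means (e.g. lead I: Q −0.50, R 0.21,
S −0.12, ST 0.08, T 0.10 mV; QRS 45 ms, QT 182 ms, T_PE 59 ms, RR 365 ms).
The healthy-control geometries are a **synthetic reference fixture** —
textbook-plausible healthy rabbit values (narrow Q, dominant R, no ST
shift, upright T) — because the study reports no control numbers.  The
derived `NORMAL_REFERENCE` parameter sets are that fixture, not measured
data.

### Recordings

A recording is a train of such beats with Gaussian beat-to-beat RR
(truncated above the beat support) plus independently switchable additive
components.  Defaults, chosen as the study conditions (the source states
sampling and filtering but no noise figures):

| component | default | rationale |
|---|---|---|
| sampling rate | 500 Hz | stated acquisition rate |
| white noise | 0.01 mV RMS | realistic for ×1000-gain lab ECG; keeps honest beat-pair QRS correlations above the 0.98 averaging gate for the small-amplitude leads (0.02 mV is used additionally in detection tests) |
| RR SD | 10 ms | sinus variability within one anesthetized recording |
| baseline wander | 0.1 mV at 0.3 Hz | respiration-scale drift |
| mains | 0.02 mV at 50 Hz | residual interference |
| ectopic rate | 0.01 / beat | "occasional" ectopy; an ectopic is a ×1.5-amplitude, ×1.6-width copy of the normal beat, which by construction fails the correlation gate (note that an amplitude-only copy would not: normalized cross-correlation is scale-invariant) |

### Cohorts

Each infarcted animal draws PIM ~ U(0.07, 0.35), VM ~ N(6.0, 0.6) g, HW ~
N(8.0, 0.8) g (resampled to keep 0 < VM ≤ HW); VIMn = PIM·VM/HW.  A
parameter with an `AllometricStructure(lead, β, δ, residual_sd,
direction)` is generated on that lead as

    log10|dev| = δ + β·log10(VIMn) + ε,   ε ~ N(0, residual_sd²)
    value = reference + direction·|dev| ... with |dev| = 10^(δ+β·log10 VIMn+ε)

so zero residual noise makes the generator the exact inverse of the
fitting module (round-trip tested to 1e−9 for arbitrary signed β, δ).
β may be signed: the published T_A row (β = −2.474, δ = −3.593) is only
self-consistent as a genuinely negative slope of log-magnitude on
log-VIMn, and the generator honors it as printed.  Parameters without a
structure scatter around the healthy reference with fixed per-parameter
SDs; QRS_A, JT and the five QTc values are *derived* from the generated
Q/R/S, QT, QRS_D and RR unless given their own structure, so the
definitional identities (QRS_A = |Q|+|R|+|S|, JT = QT − QRS_D) hold in
every cohort.

`dev_caps` optionally bounds |dev| per parameter.  The log-normal residual
has an unbounded upper tail, and a cohort that must be *rendered as beats*
needs physiological bounds (a rabbit QT cannot lengthen by 300 ms); the
end-to-end pipeline uses caps (QT ≤ 80 ms, ST ≤ 0.25 mV, ...), while all
coefficient-recovery studies run uncapped so the law stays exact.

## 2. Preprocessing (`preprocess`)

**Mains removal** — zero-phase IIR notch, Q = 80, with 3-s odd-extension
padding.  The narrow notch matters here: the piecewise-linear beats are
corner-rich and carry far more 50-Hz-region energy than smooth real ECG,
so a wide notch visibly distorts them.

**QRS detection** — the classic filter-bank chain: band-pass,
differentiation, squaring, 60-ms moving-window integration, adaptive
signal/noise peak thresholds with search-back over long gaps, and
refinement to the local positive extremum (R ≥ 0 by type; Q may exceed R
in magnitude, so the *absolute* extremum would be wrong).  The band-pass
is 8–35 Hz: the rabbit QRS (~45 ms with ~10 ms sub-waves) concentrates its
energy well above the 5–15 Hz band used for the ~90 ms human QRS — at
5–15 Hz a deep T wave out-scores the QRS in the integrator.  The
signal-peak estimate initializes from the median of the three largest
candidate peaks in the first 2 s, so a single ectopic cannot set an
unreachable threshold.  On clean synthetic recordings detection is
0-sample exact.

**Baseline correction** — one knot per beat in the flat PR region (40 ms
before R), knot value = median of ±8 ms; the natural cubic spline through
the knots is subtracted, held constant beyond the outermost knots.  Fewer
than 3 beats falls back to global-median subtraction with a warning.

**Signal averaging** — running average of 30 beats aligned on R.  Beats
whose RR deviates > 25 % from the running median RR are excluded up front
as ectopic/aberrant; remaining beats are aligned to the running template
by the integer shift (±10 ms) maximizing normalized zero-mean
cross-correlation over the QRS window (R ± 35 ms) and accepted at ≥ 0.98.
A third rejection raises the study's limit error.  Two implementation
details:

* the gate correlation is computed on 5-sample-boxcar-smoothed windows so
  it measures QRS *shape* agreement rather than the sample-noise floor
  (rabbit QRS energy is small; at realistic noise the raw pairwise
  correlation of two honest beats straddles 0.98).  The averaging itself
  uses raw beats;
* the template is seeded only with a beat that 0.98-correlates with one
  of its two successors (an aberrant first beat would poison the running
  template and reject everything after it); a failed seed consumes the
  rejection budget.

The final template is the plain mean of the accepted shifted beats, which
makes averaging permutation-invariant; window: 140 ms before R to 300 ms
after.  (100 ms pre-R would leave < 10 ms of baseline before P onset at
the study's PR of 71–76 ms — too little for the isoelectric median and the
P delineator.)

## 3. Delineation (`delineate`)

All rule constants are keyword parameters; defaults below.

| rule | default | notes |
|---|---|---|
| QRS bounds | slope threshold = 5 % of peak |dV/dt| in R ± 80 ms, 3 consecutive sub-threshold samples, slope from a 5-sample-smoothed first difference, half-width-compensated | exact on noise-free corners |
| isoelectric level | median of all samples before QRS onset | robust to the P wave (< 50 % of the window) |
| noise scale | lower-quartile of pre-QRS \|first differences\| / 0.4506 | the quartile (not the median) keeps P-wave slopes out of the estimate |
| P wave | 9-point smoothed derivative d[n] = Σⱼ j·(x[n+j]−x[n−j])/60 on the window ending 6 samples before QRS onset; presence gate 6σ_d; peak = derivative zero crossing between its extremum pair; edges where \|d\| < max(0.1·d_max, 5σ_d) for 2 samples, capped at 0.3·d_max, end compensated −1 for the kernel tail | absent P is a legal outcome |
| T peak | candidate local peaks of either sign on a 5-sample-smoothed trace, height ≥ max(3σ, 0.02 mV) vs iso *and* prominence ≥ max(3σ√(2/5), 0.006 mV); first candidate whose prominence is ≥ 70 % of the window's most prominent | height alone cannot separate a small T riding an elevated ST pedestal from a ripple on that pedestal; prominence can |
| T end | least-squares line from the peak down the descending limb to the first return within 10 % of (peak − iso), intersected with the isoelectric level | exact for the linear-tail beat model |
| ST deviation | amplitude at QRS onset + 50 ms minus iso, read as the median of the 5 samples rightward | the ST segment extends rightward from the point, so the forward median stays on the flat segment even at the limb corner |
| T amplitude | 3-sample-smoothed apex read plus first-order corner loss (a+b)/3, slopes estimated over 4-sample lags; index from a raw-dominated blend, exact on noise-free corners | a single-sample read carries the full noise σ and cannot meet the ±0.01 mV validation band |

Q and S are the signed minima between QRS onset→R and R→QRS offset,
reported absent (amplitude 0) when shallower than 0.01 mV below the
isoelectric level.

## 4. Parameters and statistics (`measure`)

Intervals come from fiducial index differences (÷ fs), amplitudes are
relative to the isoelectric level; missing fiducials propagate as NaN in
exactly the parameters that need them.  The five QT corrections operate in
seconds (RR in s, HR = 60/RR in bpm) and are reported in ms.  Fridericia
is QT/RR^(1/3), Hodge is QT + 0.00175·(HR − 60) and Matsunaga is
QT·log 600/log(1000·RR) — the standard forms of the cited formulas.  QTc
per animal is computed from that animal's QT and RR, then averaged.

Among-lead comparison per parameter: each lead's values go through the
D'Agostino–Pearson normality test; if every lead passes at α = 0.05 the
parameter is compared by one-way ANOVA with Bonferroni-corrected pairwise
t tests, otherwise Kruskal–Wallis with Dunn's rank-based post-hoc test
(tie-corrected z statistics, Bonferroni over the three contrasts, written
out here because no installed package provides it).  Leads with fewer than
8 values route to the nonparametric branch (the normality test is
undefined below that).

## 5. Allometric fitting (`allometry`)

`allometric_fit` is OLS of log10(magnitude) on log10(VIMn)
(`scipy.stats.linregress`; the test suite checks it against an independent
hand-rolled normal-equations + t-distribution oracle to 1e−10).  Zero
magnitudes are excluded (log undefined) and counted; any non-positive VIMn
is an error; fewer than 3 usable pairs is an error.  `AllometricFit.beta`
is the raw signed slope — this is what round-trips the generator exactly —
and `beta_signed = sign·|beta|` attaches the majority deviation direction,
the convention used in the ranked table (the two coincide for every
published coefficient row).  Mixed deviation signs within one parameter
warn and report the majority sign.  `beta_se`/`delta_se` are standard
errors of the regression coefficients (the most plausible reading of the
published "mean ± SD" columns); p is the two-sided slope t-test with n − 2
df, which matches the published p/r pairs at n = 9.

PIM is accepted as fraction (default) or percent via `pim_unit`;
`fit_all` fits every parameter on every lead, keeps the best lead per
parameter by |r|, ranks by |r|, and flags p < 0.05.  `mode="direct"`
regresses log10|value| itself instead of the deviation.  Note that under
this generator the direct mode is structurally weak: the raw value is
reference + deviation, not a power law of VIMn, so log|value| barely moves
when deviations are small relative to the reference — the two modes can
only agree when deviations dominate the reference.

## 6. Validation conditions and what they show

* **Delineation accuracy** is measured on 200 single-beat templates at
  500 Hz with 0.0037 mV white noise — the template-level noise after
  30-beat averaging of 0.02 mV recordings (0.02/√30).  Morphologies are
  drawn across the study's parameter ranges but restricted to shapes whose
  landmarks are geometrically well defined: a QRS whose terminal limb is
  steep enough for a slope criterion to see its offset, a T apex clearly
  distinct from the ST level, a P edge slope above the noise floor.
  Shapes outside those restrictions (e.g. the lead II infarct geometry
  with S ≈ 0, or a T equal to its ST pedestal) have no meaningful landmark
  truth; on them the delineator degrades exactly as the rules dictate
  (QRS offset lands at the S trough, the T is reported absent).
* **Coefficient recovery** generates 500 cohorts of n = 9 per published
  row with the residual SD calibrated *per cohort* so the slope standard
  error equals the published one (σ = SE·√Sxx conditional on the realized
  log-VIMn spread), then refits in deviation mode.  Mean recovered slopes
  land within ~2 % of the generating values; this validates the estimator,
  not the animal data.
* **Ranking specificity** runs on a single lead with one structured
  parameter in a clear-signal regime (residual SD 0.1).  The QT-derived
  family (QTc, JT) inherits QT's structure by definition and is excluded
  from the false-positive count.
* **Simulation sizes** (500 replicate cohorts, 200 templates, 200
  null/specificity seeds, 100-seed ranking studies) were chosen so every
  assertion sits several standard errors from its bound.

Passing these tests shows the pipeline is correct *on signals matching the
generator's assumptions*; real ECG differs (smooth waves, non-stationary
noise, biphasic T waves, drifting mains), so thresholds exposed here as
configuration should be re-examined on real recordings.

## 7. Known limitations

* The generating coefficients imply deviations spanning orders of
  magnitude across the infarct range (e.g. QT deviations of 0.1–14 ms over
  VIMn 0.05–0.2).  The sub-millisecond half of that range is below any
  delineation resolution at 500 Hz, so fits on *measured* parameters from
  the full signal pipeline are noise-limited and systematically weaker
  than fits on the true cohort parameters — visible in
  `analysis/04_allometric_fits.py`.  A single n = 10 cohort is noisy in
  exactly the way a single small animal study is.
* Normalized cross-correlation cannot reject an amplitude-only aberrant
  beat (scale invariance); rejection relies on shape (width) differences.
* The tangent T-end rule has a well-defined truth only for near-linear
  descending limbs; U waves and biphasic T decomposition are out of scope.
* The healthy reference is a documented synthetic fixture; with real
  control recordings `normal_reference_from_params` recomputes it from
  measured control templates.
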