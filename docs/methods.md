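# Methods

This note documents the models implemented in `prrtdose`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical choices that affect results.

## Kinetic models and TIAC

Measured time–activity curves (TACs) are reduced to a time-integrated
activity coefficient (TIAC, hours): the integral over time of the fraction
of injected activity in the source region.

* **Organs and tumours** (SPECT VOI concentrations at ~3, 20 and 90/120 h):
  mono-exponential `A·e^(−t/τ)` fitted by unweighted least squares on the
  linear scale (a log-scale option exists). TIAC = `A·τ`. With three points
  and two parameters a clean decaying series is fitted exactly.
* **Blood and whole body** (5 samples each): bi-exponential
  `A₁e^(−t/t₁) + A₂e^(−t/t₂)`, four-parameter least squares initialised by
  curve stripping (fit the tail from the last two positive points, subtract,
  fit the residual head), components reported fast-first (`t₁ < t₂`).
  TIAC = `A₁t₁ + A₂t₂`. Effective half-lives are `t·ln2`.
* **Trapezoid + tail fallback**: when the mono-exponential model does not
  describe a VOI series (visible uptake phase, non-decaying data, or
  R² below the model-selection threshold of 0.95 — a tie at the threshold
  goes to the parametric model), the TIAC is the trapezoid integral with
  the first measured value held constant back to t = 0 (conservative; the
  integration origin is the injection, t = 0) plus an analytic exponential
  tail `y_last/λ`. The tail rate λ is the terminal two-point slope or the
  ¹⁷⁷Lu physical decay constant (half-life 6.647 d), whichever gives the
  larger (conservative) TIAC.

**Bound on time constants.** The pipeline caps fitted time constants at the
¹⁷⁷Lu physical time constant (230 h): biological clearance can only add to
physical decay, never subtract. Without this bound a noisy, flat-looking
tail can drive `t₂` arbitrarily large and the TIAC with it. Amplitudes are
bounded too (1.0 for whole-body retention, which is a fraction of injected
activity; 50× the observed maximum otherwise) because a component much
faster than the first sample time is invisible to the data yet contributes
`A·τ` to the TIAC.

## Dose engine

Absorbed dose per administered activity follows the MIRD scheme,

```
AD/A [Gy/GBq] = TIAC [h] · 1000 [MBq/GBq] · k(E) / m [g],
k(E) = E[keV] · 5.768e-4 Gy·g·MBq⁻¹·h⁻¹,
```

with `k(E)` the local electron-deposition factor (147.9 keV mean electron
energy per ¹⁷⁷Lu decay → 0.0853 Gy·g/(MBq·h)). This replaces proprietary
S-value software with a documented, pluggable `DoseFactorTable`; it is a
good approximation for β-dominated self-dose in organs and spheres above
the 4 mL analysis threshold, and users with S-value tables can override the
per-region energies and masses. Organ masses default to CT volume × 1 g/mL.

* **Tumours**: unit-density sphere of mass = volume, after dividing the
  TIAC by the recovery coefficient `rc(v) = v/(v + c)`, `c = 4 mL` — a
  monotone saturating recovery curve with `rc(4 mL) = 0.5` and `rc → 1`,
  matching the half-recovery at the analysis threshold. Lesions under 4 mL
  are rejected rather than corrected.
* **Red marrow**: self-dose from the blood concentration TIAC times marrow
  mass (default 1170 g) and a marrow-to-blood concentration ratio of 1;
  the marrow electron energy defaults to an *effective* 81 keV, folding the
  marrow electron absorbed fraction (<1) into the local-deposition factor
  so that typical marrow TIACs (~0.18 h) yield self-doses of ~7 mGy/GBq.
  Cross-dose is the whole-body TIAC times a fixed factor, default
  3.0·10⁻⁴ Gy·GBq⁻¹ per hour of whole-body TIAC (≈11 mGy/GBq at 37 h).
  Photon cross-dose between other organs is neglected — the whole-body →
  marrow term is the only cross term computed. Missing blood samples
  propagate as an explicit flag; totals become cross-only with a warning
  and such patients are excluded listwise from red-marrow statistics.
* **Kidney BED**: linear-quadratic with a per-cycle mono-exponential
  dose-rate (Lea–Catcheside-type) factor,
  `BED_i = d_i(1 + G_i·d_i/(α/β))`, `G_i = T_rep/(T_rep + T_eff,i)`,
  defaults α/β = 2.6 Gy, T_rep = 2.8 h, full sublethal-damage repair
  between the 8-week cycles; total BED is the sum over cycles. This is the
  standard closed form for PRRT kidney dosimetry with these parameters.
  `T_eff` comes from the per-cycle kidney fit (60 h is assumed for the rare
  trapezoid fallback).

## Protocols and safety

`AD_x = AD_anchor · A_x / A_anchor` applied literally to absolute absorbed
doses (equivalent to applying it to AD/A given the relation as written).
M1 anchors cycles 2–4 on cycle 1; M2 anchors cycle 2 on cycle 1 and cycle 3
on cycle 4. Cycle-contribution fractions are reported in whole percent,
rounded half away from zero. Note that fractions recomputed from *rounded*
cohort-mean AD/A values reproduce most but not all published whole-percent
figures (kidney 22%/26%, liver first-cycle 32% and red marrow 28% do;
spleen first-cycle and liver fourth-cycle land one percent off, an artifact
of rounding the inputs) — the acceptance test checks exactly the
reproducible set. Safety comparisons treat a value *at* a limit as a breach
(conservative ≥). Extra-cycle eligibility is the largest `n ≤ 4` with
`total BED + n · BED_cycle4 ≤ limit`; the projection basis (cycle-4 or mean
per-cycle BED) is an option, cycle 4 by default as the closest predictor of
a hypothetical cycle 5.

## Agreement statistics

Bland–Altman on paired differences in Gy (and, in the report, per-patient
percent differences, which differ from the percent difference of cohort
means for skewed dose distributions): limits of agreement `μΔ ± z·σΔ` and
CI of the mean difference `μΔ ± z·σΔ/√n`, with the Gaussian quantile
`z = z₀.₉₇₅ ≈ 1.96` (not a t quantile) and the n−1 sample SD — the
combination validated by reconstructing published CIs from published LOAs.
Out-of-bound percentages use a closed LOA interval (boundary = inside) and
one-decimal rounding. Wilcoxon signed-rank drops zero differences, uses the
exact null distribution up to n = 25 and a continuity-corrected normal
approximation above; differences at float resolution (<1e-9 of the dose
scale) are treated as ties so that noiseless constant-kinetics cohorts
degenerate to p = 1 rather than testing numerical dust. Fisher's exact test
and the covariate-adjusted OLS go through scipy/statsmodels; tests validate
them against exhaustive enumeration and normal-equation oracles. The TIAC
trend test reports the per-patient cycle I − cycle IV difference (so an
increasing TIAC gives a negative mean).

## Synthetic cohort: what it emulates

Defaults describe a 30-patient cohort treated with four cycles of
7.2 ± 0.4 GBq (range 6.3–7.7 GBq). The administered-activity law is a
truncated normal whose pre-truncation location is calibrated (by root
finding) so the *realized* truncated mean equals the configured 7.2 GBq;
the Monte-Carlo test checks the generated grand mean against this analytic
value.

Ground-truth kinetics per patient and cycle:

* organs are mono-exponential (matching the fit family, so recovery tests
  are well-posed) with per-cycle mean TIAC targets encoding the cycle
  drifts — kidney 1.7→1.9 h (rising ~0.2 h cycle I→IV), spleen ~flat
  1.6→1.7 h, liver declining ~26% over four cycles from a burden-dependent
  baseline (`2 + 55·burden` h, spanning ~2–57 h across burdens);
* kidney uptake is coupled negatively to liver tumour burden
  (factor `1 − 0.3·burden`), reproducing the sign of the published
  burden–kidney-dose association;
* tumour lesions (1 + Poisson(0.4) per patient, lognormal volumes with
  22 mL median, floored at the 4 mL threshold, site-dependent uptake with
  bone/node lower than liver/pancreas) decline geometrically at ratio 0.8
  per cycle, putting cycle contributions near 34%→17%;
* blood and whole body are bi-exponential; the whole-body cycle-1 default
  is exactly the tabulated cohort mean (0.58/0.38 amplitudes, 2.58/89.3 h
  time constants, amplitude sum 0.96), with the slow time constant shrinking
  over cycles (whole-body TIAC ~35→25 h) and blood scaled to marrow TIACs
  of ~0.18–0.19 h;
* within-patient cycles share a lognormal patient factor with inter-cycle
  correlation 0.9 (the study does not report this correlation; it is an
  exposed parameter, set high because repeated kinetics in one patient are
  strongly similar);
* measurement noise is multiplicative mean-one lognormal, CV 10% by
  default (concentrations are positive and heteroscedastic); sample times
  get ±0.25 h uniform jitter and the 90/120 h outpatient point is drawn
  once per patient from U[90, 120] h and reused across cycles;
* three patients lack blood samples entirely, emulating the samples never
  collected in the study cohort.

Effective half-lives are capped below the ¹⁷⁷Lu physical half-life, tumour
volumes at ≥4 mL, whole-body amplitude sums at ≤1. Counts-to-activity
calibration is not simulated (whole-body series are generated directly as
fractions of injected activity), and neither are image formation,
partial-volume physics beyond the recovery curve, organ overlap,
attenuation, or splenectomy. Passing tests therefore validate the
*computational chain* — fitting, dose conversion, protocol extrapolation,
statistics — under realistic kinetics and noise, not the imaging chain that
produces VOI concentrations in a clinic.

## Problem sizes and determinism

Everything is deterministic given `rng_seed`; every series derives its own
RNG stream from (seed, patient, kind, region, cycle), so a single series can
be re-simulated in isolation bit-exactly. Tests use cohorts of 3–30
patients; the protocol-property acceptance test runs 20 seeds of 30
patients on analytic (truth-derived) doses, and end-to-end fitting checks
use small noiseless cohorts — sizes chosen to exercise every path while
keeping the default suite to roughly a minute.

## Known limitations

* The local-deposition dose factor ignores photon dose and electron escape
  from small organs; it reproduces β-dominated organ-dose magnitudes but is
  not a substitute for patient-specific S-values at the organ level.
* The red-marrow model is the blood-based surrogate, not an image-based
  marrow dosimetry.
* The BED expression assumes mono-exponential dose-rate decay per cycle and
  complete inter-cycle repair.
* Simplified-protocol bias measured on the synthetic cohort depends on the
  configured drifts; the defaults reproduce published trends in sign and
  approximate magnitude, but patient-level published statistics are not
  reproducible without the original data.
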