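# prrtdose

Per-cycle internal dosimetry for radioligand therapy (RLT/PRRT) with
[¹⁷⁷Lu]Lu-DOTATATE, and a framework for validating **simplified dosimetry
protocols** against full per-cycle dosimetry.

Patients with neuroendocrine neoplasms typically receive four cycles of
~7.4 GBq of [¹⁷⁷Lu]Lu-DOTATATE. Measuring absorbed doses after *every*
cycle (the reference protocol, **M0**) is accurate but costly: three
SPECT/CT sessions, five blood samples and five whole-body counts per cycle.
Simplified protocols extrapolate instead:

* **M1** — dosimetry after cycle 1 only; later cycles are scaled by
  administered activity, `AD_x = AD_1 · A_x / A_1`;
* **M2** — dosimetry after cycles 1 and 4; cycle 2 is scaled from cycle 1
  and cycle 3 from cycle 4.

Because organ and tumour kinetics drift over the course of therapy (kidney
uptake rises as tumour uptake falls), M1 and M2 are biased in predictable
directions. This package provides everything needed to quantify that bias
on real or synthetic data, for medical physicists and method developers.

## What is inside

| module | contents |
| --- | --- |
| `prrtdose.biokinetics` | time–activity curve fitting (mono-/bi-exponential with curve-stripping initialisation, trapezoid + analytic tail), TIAC computation, effective half-lives `T_eff = t·ln2` |
| `prrtdose.dose` | MIRD-style dose engine: organ self-dose from TIAC and mass (local electron-deposition factor, pluggable), sphere-model tumour dose with recovery-coefficient correction `rc(v) = v/(v+4 mL)`, red-marrow self (blood) + cross (whole body) dose, kidney BED under the LQ model `BED_i = d_i (1 + G_i d_i/(α/β))`, `G_i = T_rep/(T_rep + T_eff,i)` |
| `prrtdose.protocols` | M0/M1/M2 cumulative doses, cycle-contribution fractions, safety limits (kidney 23 Gy; BED 28/40 Gy; red marrow 2 Gy), extra-cycle eligibility |
| `prrtdose.agreement` | Bland–Altman limits of agreement `μΔ ± z₁₋α/₂·σΔ` with CI `μΔ ± z·σΔ/√n`, out-of-bound fraction, Wilcoxon signed-rank, Fisher's exact test, covariate-adjusted regression, cycle I-vs-IV TIAC trend test |
| `prrtdose.cohort` | synthetic-cohort generator with per-patient ground truth (30 virtual patients by default, calibrated cycle drifts, lognormal measurement noise) |
| `prrtdose.pipeline` / `prrtdose.cli` | simulate → dose → compare pipeline over tidy CSV/JSON files, with a thin `prrtdose` command-line wrapper |

## Worked example

Fit the cohort-mean whole-body retention curve
`FIA(t) = 0.58·e^(−t/2.58) + 0.38·e^(−t/89.3)` sampled at the probe
schedule (`examples/whole_body_fit.py`):

```
amplitudes A1, A2        : [0.58 0.38]
time constants t1, t2 [h]: [ 2.58 89.3 ]
effective half-lives [h] : 1.79 (rapid), 61.9 (slow)
whole-body TIAC [h]      : 35.43
```

The rapid 1.79 h component is early renal clearance of unbound peptide, the
slow 61.9 h component is washout of tissue-bound activity, and the 35.4 h
TIAC is the whole-body residence time feeding the red-marrow cross dose.

Compare protocols on a synthetic cohort (`examples/protocol_agreement.py`,
abridged):

```
    region     pair  n  mean_pct_diff  wilcoxon_p  loa_low_gy  loa_high_gy
    kidney M1_vs_M0 30         -7.981       0.001      -4.431        1.942
    kidney M2_vs_M0 30         -2.792       0.010      -2.014        1.193
     liver M1_vs_M0 30         18.836       0.000      -4.231       13.466
     liver M2_vs_M0 30          2.679       0.019      -2.832        4.166
     tumor M1_vs_M0 40         33.029       0.000     -94.217      204.039
     tumor M2_vs_M0 40         -0.635       0.793     -54.290       57.839
```

M1 underestimates the kidney dose by ~8% and overestimates liver and tumour
doses by ~19% and ~33% (its single anchor predates the drift); M2 stays
within a few percent everywhere. Other examples cover the kidney BED with
extra-cycle eligibility and the noiseless end-to-end closure check.

The same pipeline runs from the shell:

```bash
prrtdose simulate --seed 1 --n 30 --out run/
prrtdose dose --measurements run/measurements.csv \
              --administrations run/administrations.csv --out run/
prrtdose compare --doses run/doses.csv --out run/
```

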