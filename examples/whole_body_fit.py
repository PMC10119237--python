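"""Fit a whole-body retention curve and read off its effective half-lives.

Builds the cohort-mean whole-body retention FIA(t) = 0.58 exp(-t/2.58)
+ 0.38 exp(-t/89.3), samples it at the external-probe schedule
(1, 1.5, 4, 20, 90 h post infusion), refits the bi-exponential model and
prints the recovered parameters, half-lives and TIAC.
"""

import numpy as np

from prrtdose import (MeasurementSeries, biexp, compute_tiac,
                      effective_half_life, fit_biexp)

times = np.array([1.0, 1.5, 4.0, 20.0, 90.0])
values = biexp(times, 0.58, 0.38, 2.58, 89.3)
series = MeasurementSeries("demo", 1, "wb", "whole_body", times, values,
                           unit="FIA")

fit = fit_biexp(series)
fast_hl, slow_hl = effective_half_life(fit)

print("amplitudes A1, A2        :", np.round(fit.amplitudes, 3))
print("time constants t1, t2 [h]:", np.round(fit.time_constants, 2))
print(f"effective half-lives [h] : {fast_hl:.2f} (rapid), {slow_hl:.1f} (slow)")
print(f"whole-body TIAC [h]      : {compute_tiac(fit):.2f}")
print()
print("The rapid component is early renal clearance of the unbound peptide;")
print("the slow component is washout of tissue-bound activity. The TIAC is")
print("the area under the retention curve: the residence time that drives")
print("the whole-body-to-red-marrow cross dose.")
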