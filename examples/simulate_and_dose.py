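"""Simulate a small noiseless cohort and verify the dose pipeline recovers
the generator's analytic doses.

Generates two virtual patients with zero measurement noise, runs the full
fit -> TIAC -> dose chain on their measurement series, and compares every
per-cycle absorbed dose with the dose computed directly from the
ground-truth kinetics.
"""

import numpy as np
import pandas as pd

from prrtdose import CohortConfig, generate_cohort, pipeline

cfg = CohortConfig(n_patients=2, rng_seed=4, noise_cv=0.0, n_missing_blood=0)
truths, series = generate_cohort(cfg)
activities = {(t.patient_id, c): t.activities_gbq[c - 1]
              for t in truths for c in (1, 2, 3, 4)}

doses, fits = pipeline.compute_cycle_doses(series, activities)
truth_doses = pd.concat([pipeline.analytic_cycle_doses(t) for t in truths])
merged = doses.merge(truth_doses, on=["patient_id", "cycle", "region"],
                     suffixes=("", "_truth"))
rel_err = np.abs(merged.ad_gy - merged.ad_gy_truth) / merged.ad_gy_truth

print(f"patients: {len(truths)}, measurement series: {len(series)}, "
      f"fitted dose rows: {len(doses)}")
print(doses[doses.patient_id == "P001"]
      .query("cycle == 1")[["region", "ad_per_activity_gy_per_gbq", "ad_gy"]]
      .round(3).to_string(index=False))
print(f"max relative error vs analytic truth: {rel_err.max():.2e}")
print()
print("With no measurement noise every fit is exact, so the recomputed")
print("doses match the generating kinetics to numerical precision; this is")
print("the closure check that validates the fitting and dose engines.")
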