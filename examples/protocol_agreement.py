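"""Compare simplified dosimetry protocols (M1, M2) with full per-cycle
dosimetry (M0) on a synthetic 30-patient cohort.

Generates the default drift-calibrated cohort (kidney uptake rising over
cycles, liver/whole-body/tumour falling), computes per-cycle doses from the
ground-truth kinetics, assembles cumulative doses under M0/M1/M2 and prints
the agreement table: mean percent difference, Wilcoxon p, Bland–Altman
limits of agreement and out-of-bound percentage per region.
"""

import pandas as pd

from prrtdose import CohortConfig, generate_cohort, pipeline

cfg = CohortConfig(n_patients=30, rng_seed=1)
truths, _ = generate_cohort(cfg)
doses = pd.concat([pipeline.analytic_cycle_doses(t) for t in truths])

report = pipeline.run_compare(doses)
cols = ["region", "pair", "n", "cad_m0_mean_gy", "mean_pct_diff",
        "sd_pct_diff", "wilcoxon_p", "loa_low_gy", "loa_high_gy",
        "pct_out_of_bounds"]
print(report["table"][cols].round(3).to_string(index=False))
print()
print("extra-cycle eligibility (kidney BED, 28 Gy limit):",
      report["extra_cycle_counts"])
print(f"mean kidney BED: {report['bed']['mean_total_bed_gy']:.1f} Gy")
print()
print("M1 (cycle-1 anchor) underestimates the kidney dose (its uptake rises")
print("after cycle 1) and overestimates liver, red marrow and tumour doses")
print("(their uptake falls); M2 (cycle 1 + 4 anchors) brackets the drift and")
print("stays within a few percent of the per-cycle reference.")
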