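"""Simulate a cohort, bin it, and refit the uACR-on-uPCR calibration.

Generates a synthetic three-visit cohort whose median uACR follows the
published non-diabetic curve, summarizes uACR per 0.01-g/gCr uPCR bin,
chooses the knot count by AIC, and fits the piecewise log-linear spline.
"""

import numpy as np

from albupred import (
    CohortTruth,
    apply_eligibility,
    bin_summaries,
    generate_cohort,
    pooled_measurements,
    select_knot_count,
    slope_change_tests,
)
from albupred.core_data import cohort_from_frame

truth = CohortTruth(n_patients=197, diabetes_fraction=0.0, seed=1)
cohort = cohort_from_frame(generate_cohort(truth))
kept, excluded = apply_eligibility(cohort)
print(f"{len(kept)} of {len(cohort)} synthetic patients eligible "
      f"({len(excluded)} excluded)")

records = pooled_measurements(kept)
pairs = [(u, a) for u, a in zip(records.upcr, records.uacr)
         if 0 < u <= 0.50 and a > 0]
bins = [b for b in bin_summaries(pairs) if b.bin_label > 0]
print(f"{len(bins)} occupied uPCR bins; e.g. bin 0.09 g/gCr:")
b09 = next(b for b in bins if b.bin_label == 0.09)
print(f"  n={b09.n}, median uACR {b09.median_uacr:.1f} "
      f"(IQR {b09.q1:.1f}-{b09.q3:.1f}) mg/gCr")

x = np.log([b.bin_label * 1000 for b in bins])
y = np.log([b.median_uacr for b in bins])
raw = records.loc[records.upcr > 0, "upcr"].to_numpy() * 1000
best_k, aic_table, model = select_knot_count(x, y, "linear",
                                             raw_values=raw)
print(f"AIC selects {best_k} knots: "
      + ", ".join(f"k={k}: {v:.1f}" for k, v in aic_table.items()))
print(f"knots at {np.round(model.knots, 0)} mg/gCr, "
      f"adjusted R^2 {model.adj_r2:.3f}")
for seg, change in zip(model.segments[1:], slope_change_tests(model)):
    print(f"  slope change at {seg.lo:.0f} mg/gCr: "
          f"{change.difference:+.2f} (p={change.p:.2f})")
print("A positive slope change in the tens of mg/gCr marks where uACR "
      "starts rising steeply with uPCR; at ~600 visits the AIC choice "
      "between 3 and 4 knots is close, as the AIC table shows.")
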