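"""Same-sample stability: repeated measurement agreement and cutoffs.

Generates a synthetic substudy in which each urine sample is assayed
fresh, after 3-4 h refrigeration, and twice after 3-4 days frozen, then
summarizes stratified agreement and per-occasion diagnostic cutoffs.
"""

from albupred import (
    StabilityTruth,
    generate_stability_study,
    stability_cutoffs,
)
from albupred.stability import agreement_table

samples = generate_stability_study(StabilityTruth(n_samples=88, seed=1))

print("Urinary protein agreement, fresh vs freeze-thaw (pair 1-3), by")
print("mean concentration stratum (r collapses only for trace protein):")
table = agreement_table(samples, "up", pairs=((1, 3),))
print(table[["stratum", "n", "slope", "intercept", "r",
             "bias_median"]].round(3).to_string(index=False))

print("\nPer-occasion cutoffs for uACR >= 30 mg/gCr:")
cuts = stability_cutoffs(samples)
same = cuts[(cuts["target"] == "same_occasion") & ~cuts["degenerate"]]
print(same[["occasion", "condition", "upcr_cutoff", "upcr_auc",
            "up_cutoff", "up_auc", "auc_diff_p"]].round(3)
      .to_string(index=False))
print("\nThe uPCR cutoff stays near 0.07-0.09 g/gCr across storage")
print("conditions, and uPCR discriminates better than the raw protein")
print("concentration (positive AUC difference), because creatinine")
print("correction removes urine-dilution noise.")
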