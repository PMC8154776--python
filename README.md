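# albupred

Predicting **microalbuminuria from proteinuria** in chronic kidney
disease (CKD).

Albuminuria (urinary albumin-to-creatinine ratio, uACR ≥ 30 mg/gCr) is
the guideline marker of early kidney damage, but in many settings only
total urinary protein (uPCR, g/gCr) is measured routinely. The
conventional equivalence — uPCR 0.15 g/gCr ≈ uACR 30 mg/gCr — turns out
to sit far above the proteinuria level at which microalbuminuria
actually begins in adults with lifestyle-related disease. `albupred`
implements the full analysis pipeline for quantifying that relationship
and deriving practical uPCR screening cutoffs:

- **Data model** (`albupred.core_data`): unit-correct derivation of
  uPCR = uP/uCr (g/gCr) and uACR = uAlb·100/uCr (mg/gCr) from assay
  concentrations with detection-limit censoring; eGFR (Japanese
  Society of Nephrology equation, 194·sCr⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷, ×0.739 if
  female) and KDIGO GFR staging; the repeated-measurement albuminuria
  rule (a category on ≥ 2 of 3 visits; one visit in each category counts
  as microalbuminuria); cohort eligibility filtering.
- **Calibration** (`albupred.calibration`): median uACR per 0.01-g/gCr
  uPCR bin; continuous piecewise log-linear (“mkspline”-style) and
  restricted cubic spline fits of ln(median uACR) on ln(uPCR) with knots
  at standard percentiles (5/35/65/95 for k = 4); AIC knot-count
  selection; slope-change t tests at each knot; closed-form forward and
  inverse prediction; a registry of published coefficient sets.
- **ROC machinery** (`albupred.roc`): empirical ROC curves with tie
  handling, Mann–Whitney AUC with DeLong standard errors, Youden-index
  cutoffs (J = Se + Sp − 1, ties broken toward higher sensitivity), and
  the DeLong test for correlated AUCs.
- **Cohort analyses** (`albupred.cohort`): single and summed uPCR
  discriminators of patient-level microalbuminuria, per-threshold uACR
  tables, subgroup cutoffs (age/sex/GFR/diabetes), uPCR × uACR
  cross-tabulations, and ΔuACR-on-ΔuPCR regressions.
- **Sample stability** (`albupred.stability`): intra/interday agreement
  of repeated measurements of the same sample (fresh, refrigerated,
  freeze-thawed), stratified by concentration, plus per-occasion cutoffs.
- **Synthetic cohorts** (`albupred.simulate`): seeded generators that
  emulate the joint (uPCR, uACR) structure, within-patient correlation,
  GFR mix, censoring, and storage noise, so every stage is testable
  end to end without patient data.

## Worked example

```python
from albupred import (load_published_model, predict_median_uacr,
                      invert_median_uacr)

model = load_published_model("all")        # uPCR in mg/gCr throughout
predict_median_uacr(model, 150.0)          # -> 77.58  (median uACR, mg/gCr)
invert_median_uacr(model, 30.0) / 1000     # -> 0.0767 (uPCR, g/gCr)
```

At the conventional proteinuria boundary of 0.15 g/gCr the expected
median uACR is already ≈ 78 mg/gCr — well inside the microalbuminuric
range — while median uACR 30 mg/gCr corresponds to uPCR ≈ 0.077 g/gCr,
about half the conventional boundary. The scripts in `examples/` walk
through each capability (conversion, simulate-and-refit, cutoff
derivation, stability substudy) and print annotated output; a thin CLI
offers the same as subcommands:

```sh
albupred convert --population non_diabetic --uacr 30
albupred simulate --out sim --seed 1
albupred report --input sim/cohort.csv --out report
albupred stability --input sim/stability.csv --out stab
```

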