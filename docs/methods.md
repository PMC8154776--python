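# Methods

## The estimation problem

In adults with lifestyle-related disease and low-grade proteinuria
(uPCR < 0.5 g/gCr), we want (i) a calibration from spot-urine uPCR to
the expected *median* uACR, and (ii) operating thresholds of uPCR (and
of sums of repeated uPCRs) that discriminate microalbuminuria. Both
ratios are dilution-corrected: uPCR = uP/uCr is g protein per g
creatinine when both concentrations are in mg/dl, and
uACR = uAlb·100/uCr is mg albumin per g creatinine when albumin is in
mg/l and creatinine in mg/dl. Concentrations below the assay detection
limit are stored as numeric zero with a censoring flag, and enter
analyses as zero except where a logarithm or a ratio of ratios would be
undefined, in which case the record is dropped from that computation.

Patients are classified from three visits: a per-visit uACR category
(< 30 normo, 30–299 micro, ≥ 300 mg/gCr macro) and a patient category
equal to any category reached on at least two visits; when the three
visits fall in three different categories the patient is classified as
microalbuminuric (the intermediate state). Eligibility requires
first-visit uPCR < 0.5 g/gCr and eGFR ≥ 15 ml/min/1.73 m²; patients
whose eGFR drops ≥ 30% between measurements ≤ 92 days apart are
excluded (a drop of exactly 30% excludes), while proteinuria rising to
≥ 0.5 g/gCr on a later visit never excludes. eGFR uses the Japanese
Society of Nephrology creatinine equation by default
(194·sCr⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷, ×0.739 for women; pluggable coefficients),
and the GFR category comes from the mean of all available eGFR values
(the averaging window is a convention; we average everything supplied).
KDIGO stage boundaries are half-open with the lower edge inclusive.

## Spline calibration

The calibration regresses y = ln(median uACR) on x = ln(uPCR), with
uPCR in mg/gCr. Observations are the occupied 0.01-g/gCr bins of the
raw (uPCR, uACR) pairs up to 0.50 g/gCr: bin membership is
nearest-multiple rounding, the bin label is the rounded value, and the
bin's median/IQR use linear interpolation between order statistics
(type-7). Bins with label 0 (undetected or sub-resolution uPCR) cannot
enter a log fit and are excluded. The regression is unweighted by
default; weighting by bin count is available (`fit_linear_spline(...,
weights=...)`) because bin medians are heteroscedastic, but in our
experiments it did not materially improve outer-segment estimates, so
nothing uses it by default.

The piecewise-linear fit uses the continuous basis x₁ = min(x, k₁),
xⱼ = clamp(x − kⱼ₋₁, 0, kⱼ − kⱼ₋₁), x_{m+1} = max(x − k_m, 0), so each
basis coefficient *is* a segment slope; per-segment intercepts are
cumulated from continuity. Knots sit at standard percentiles of the raw
detected measurement distribution (10/50/90 for k = 3, 5/35/65/95 for
k = 4, 5/27.5/50/72.5/95 for k = 5). The restricted cubic spline uses
the truncated-power natural-spline basis (linear beyond the boundary
knots). Both fits report AIC under the shared Gaussian convention
AIC = n·ln(RSS/n) + 2(p+1), so knot counts and spline families are
comparable; ties in knot-count selection go to the smaller k. Slope
changes across interior knots are contrasts c'β with variance c'Vc from
the coefficient covariance, referred to a Student t on the residual
degrees of freedom; an exact-fit degeneracy (se ≈ 0, diff ≈ 0) reports
t = 0, p = 1 rather than 0/0.

Forward prediction locates the segment containing uPCR and returns
exp(a + b·ln uPCR); no extrapolation outside the model domain. Inversion
solves the segment equations in closed form and requires all slopes
positive (piecewise monotone); published coefficient sets for the
overall, non-diabetic and diabetic populations ship as JSON package
data, and the registry loader accepts external files with the same
schema so other published conversion equations can be plugged in (none
are bundled; their coefficients are not reproduced here).

## ROC and cutoffs

The ROC machinery is empirical and from scratch: candidate thresholds
are the unique observed scores plus a sentinel above the maximum, a
subject is positive when score ≥ threshold, AUC is the Mann–Whitney
statistic P(pos > neg) + ½P(pos = neg), and its variance comes from
DeLong structural components (also used for the paired comparison of two
correlated AUCs; the p value against AUC = 0.5 is a two-sided normal
test). The Youden-optimal cutoff maximizes J = Se + Sp − 1; ties are
broken toward the larger sensitivity, i.e. the lower threshold. Cutoffs
are kept at full precision internally and rounded only for display.
Per-measurement analyses pool each patient's visits as independent
records with no clustering correction, matching the design being
emulated; patient-level analyses use one row per patient.

## Synthetic data

The cohort generator draws, per patient i and visit j:
ln uPCRᵢⱼ = g(zᵢ + eᵢⱼ), where zᵢ ~ N(0, √ICC), eᵢⱼ ~ N(0, √(1−ICC)),
ICC = 0.73, and g is a monotone piecewise-linear quantile transform
anchored so that the 5th/35th/65th/95th percentiles of the *detected*
visits land at 20/60/120/350 mg/gCr with ~7% of visits censored — a
plain lognormal cannot reproduce all four anchors, so the marginal is
deliberately skewed. Then ln uACRᵢⱼ = f(ln uPCRᵢⱼ) + s·(bᵢ + εᵢⱼ) with
f the population's piecewise log-linear curve (end segments extended
beyond the published domain), bᵢ ~ N(0, 0.45) a patient effect and
εᵢⱼ ~ N(0, 0.40) visit noise (total sd ≈ 0.6, sized so synthetic bin
IQR ratios match the binned-table spread at low uPCR). The factor s
tapers linearly in ln uPCR from 1 at 0.2 g/gCr to 0.25 at 0.5 g/gCr:
above ~0.2 g/gCr albumin dominates urinary protein and uACR couples
directly to uPCR, so a flat residual would overstate high-range
scatter. Concentrations are back-computed through a drawn urinary
creatinine (lognormal, median 65 mg/dl, ln-sd 0.5): uP = uPCR·uCr,
uAlb = uACR·uCr/100, censored below configurable detection limits
(defaults 0.8 mg/dl protein, 2.0 mg/l albumin, calibrated to give the
observed ~7% undetected proteinuria). Serum creatinine is made
consistent with the patient's assigned GFR category (stratum-specific
category mix) by inverting the eGFR equation; visit days use intervals
of ~84 and ~75 days (sd ~61, floored at 14). All randomness flows from
one seed through per-patient spawned substreams, so output is
bit-identical for a given seed and individual patients are stable.

The stability generator gives each sample a true (uP, uCr) pair, a true
uACR from the overall curve plus residual, and four measurements:
fresh, refrigerated (3–4 h), and two consecutive assays of one
freeze-thawed aliquot (which therefore share a storage perturbation).
Each measurement multiplies the truth by exp(storage shift + assay
noise); urinary protein additionally receives an *additive* storage
perturbation (sd 0.8 mg/dl) — an absolute trace-level effect that is
negligible at high concentrations but destroys the correlation of
stored measurements below ~3 mg/dl, reproducing the observed pattern in
which only trace proteinuria becomes irreproducible after storage while
creatinine is essentially exact everywhere.

What the generators do **not** emulate: real assay rounding ladders,
comorbidity structure, longitudinal eGFR trajectories beyond the
eligibility check, non-random visit scheduling, or any systematic
storage *bias* (shifts are zero-mean). Passing tests therefore
demonstrate that the pipeline recovers known structure from data of the
assumed form, not that the bundled coefficients generalize to other
laboratories or populations.

## Test scale and numerical choices

Recovery tests run at the emulated study's scale (≈ 200 patients × 3
visits; 88 or 500 stability samples), which keeps the full suite under
a minute. At that scale the interior spline segments rest on ~6 bin
medians each, so refitted segment slopes carry standard errors around
0.3; the slope-recovery check asserts a ±0.2 tolerance that is tighter
than this sampling noise and is expected to fail for some seeds — it is
kept at the stated tolerance deliberately rather than loosened, and the
AIC knot-count recovery is instead verified in the large-n/small-noise
regime where it is identifiable. Percentile and IQR computations use
linear interpolation throughout; Youden ties use an absolute 1e-12
comparison; the paired DeLong test returns p = 1 when the variance of
the difference is exactly degenerate (identical score vectors).

## Known limitations

The bundled coefficients describe one population and assay suite;
conversion equations of this kind are laboratory-dependent, and the
registry exists precisely so locally refit coefficients can be swapped
in. The per-measurement pooled analyses ignore within-patient
correlation by design. Detection limits are configurable defaults, not
asserted assay properties. The inverse mapping is only defined where
the fitted spline is monotone increasing.
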