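"""Seeded synthetic-data generators.

Two generators emulate the data the analysis pipeline consumes:

* a lifestyle-disease CKD cohort with three spot-urine visits per
  patient, whose joint (uPCR, uACR) structure follows a published
  piecewise log-linear median curve per diabetes stratum, with lognormal
  uPCR, within-patient correlation across visits, a KDIGO GFR-category
  mix, detection-limit censoring, and serum creatinine consistent with
  the assigned GFR via the eGFR equation;

* a same-sample stability substudy in which each sample is measured
  fresh, after refrigeration, and twice after freeze-thaw, with
  multiplicative measurement error per storage condition and inflated
  storage noise for low-protein samples.

All randomness flows from one explicit seed; per-patient substreams are
spawned so individual patients are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import SplineModel, load_published_model
from .core_data import COHORT_COLUMNS
from .stability import StabilitySample

__all__ = [
    "CohortTruth",
    "StabilityTruth",
    "generate_cohort",
    "generate_stability_study",
    "truth_upcr_at_uacr",
]

#: eGFR sampling range (ml/min/1.73 m^2) per KDIGO category.
_GFR_RANGES = {
    "G1": (90.0, 120.0), "G2": (60.0, 90.0), "G3a": (45.0, 60.0),
    "G3b": (30.0, 45.0), "G4": (15.0, 30.0),
}

#: Observed GFR-category mix per diabetes stratum (patient proportions).
_GFR_MIX = {
    False: {"G1": 5 / 197, "G2": 47 / 197, "G3a": 73 / 197,
            "G3b": 44 / 197, "G4": 28 / 197},
    True: {"G1": 12 / 106, "G2": 45 / 106, "G3a": 26 / 106,
           "G3b": 16 / 106, "G4": 7 / 106},
}

_MALE_FRACTION = {False: 124 / 197, True: 70 / 106}


@dataclass
class CohortTruth:
    """Ground-truth parameters of the synthetic cohort.

    The marginal visit distribution of ln uPCR is a monotone
    piecewise-linear quantile transform of a standard normal, anchored so
    that the 5th/35th/65th/95th percentiles of the *detected*
    measurements (those above the urinary-protein detection limit, about
    93% of visits) fall at the published knots 20/60/120/350 mg/gCr —
    i.e. the generator reproduces the skewed study distribution rather
    than a plain lognormal.  Within-patient correlation across visits is
    set by ``upcr_icc`` (share of ln-uPCR variance between patients).
    The ln-scale uACR residual around the median curve is split into a
    patient effect and visit noise with total sd ~0.6, sized so synthetic
    bin IQRs resemble the published bin IQR widths.
    """

    n_patients: int = 303
    diabetes_fraction: float = 106 / 303
    age_mean: float = 68.9
    age_sd: float = 14.8
    age_bounds: tuple[float, float] = (18.0, 100.0)
    curve_population: dict | None = None   # diabetes flag -> SplineModel
    upcr_anchor_knots: tuple[float, ...] = (20.0, 60.0, 120.0, 350.0)
    upcr_anchor_percentiles: tuple[float, ...] = (5.0, 35.0, 65.0, 95.0)
    assumed_censored_fraction: float = 0.074
    upcr_icc: float = 0.73
    uacr_patient_sd: float = 0.45
    uacr_visit_sd: float = 0.40
    uacr_taper_start: float = 200.0        # mg/gCr
    uacr_taper_end: float = 500.0
    uacr_taper_floor: float = 0.25
    ln_ucr_mean: float = float(np.log(65.0))   # ln(mg/dl)
    ln_ucr_sd: float = 0.5
    up_detection_limit: float = 0.8        # mg/dl
    ualb_detection_limit: float = 2.0      # mg/l
    visit_interval_means: tuple[float, float] = (84.4, 75.0)
    visit_interval_sds: tuple[float, float] = (60.8, 61.8)
    min_interval_days: float = 14.0
    egfr_visit_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.diabetes_fraction <= 1:
            raise ValueError("diabetes_fraction must be in [0, 1]")
        for name in ("uacr_patient_sd", "uacr_visit_sd", "ln_ucr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.upcr_icc < 1:
            raise ValueError("upcr_icc must be in (0, 1)")
        if self.curve_population is None:
            self.curve_population = {
                False: load_published_model("non_diabetic"),
                True: load_published_model("diabetic"),
            }


def _upcr_quantile_transform(truth: "CohortTruth"):
    """Monotone map from a standard-normal deviate to ln uPCR (mg/gCr).

    Anchors are placed so the stated percentiles of the detected portion
    of the marginal (after removing the assumed censored fraction from
    the bottom) land at the anchor knots; linear in z between anchors and
    extended with the outer-segment slopes beyond them.
    """
    from scipy import stats

    c = truth.assumed_censored_fraction
    p = np.asarray(truth.upcr_anchor_percentiles, dtype=float) / 100.0
    zk = stats.norm.ppf(c + p * (1.0 - c))
    lnk = np.log(np.asarray(truth.upcr_anchor_knots, dtype=float))
    s_lo = (lnk[1] - lnk[0]) / (zk[1] - zk[0])
    s_hi = (lnk[-1] - lnk[-2]) / (zk[-1] - zk[-2])

    def g(z):
        z = np.asarray(z, dtype=float)
        out = np.interp(z, zk, lnk)
        out = np.where(z < zk[0], lnk[0] + s_lo * (z - zk[0]), out)
        out = np.where(z > zk[-1], lnk[-1] + s_hi * (z - zk[-1]), out)
        return out

    return g


def _predict_ln_extrapolated(model: SplineModel, ln_upcr: float) -> float:
    """Evaluate the piecewise-linear truth curve, extending the end
    segments beyond the published domain (the generator may draw uPCR
    outside it)."""
    upcr = float(np.exp(ln_upcr))
    segs = model.segments
    for seg in segs:
        if seg.lo <= upcr < seg.hi:
            return seg.intercept + seg.slope * ln_upcr
    seg = segs[0] if upcr < segs[0].hi else segs[-1]
    return seg.intercept + seg.slope * ln_upcr


def truth_upcr_at_uacr(model: SplineModel, target_uacr: float = 30.0) -> float:
    """uPCR (g/gCr) at which the truth median curve crosses ``target_uacr``."""
    ln_t = np.log(target_uacr)
    for seg in model.segments:
        y_lo = seg.intercept + seg.slope * np.log(max(seg.lo, 1e-9))
        y_hi = seg.intercept + seg.slope * np.log(seg.hi)
        if y_lo <= ln_t <= y_hi:
            return float(np.exp((ln_t - seg.intercept) / seg.slope)) / 1000.0
    raise ValueError("target not crossed within the curve's segments")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def _serum_cr_for_egfr(egfr, age, sex):
    """Invert the eGFR equation for serum creatinine (mg/dl)."""
    base = 194.0 * age**-0.287 * (0.739 if sex == "female" else 1.0)
    return float((egfr / base) ** (-1.0 / 1.094))


def generate_cohort(truth: CohortTruth) -> pd.DataFrame:
    """Generate the one-row-per-visit cohort table.

    Per patient i and visit j: ln uPCR_ij = mu_i + e_ij and
    ln uACR_ij = f(ln uPCR_ij; stratum curve) + b_i + eps_ij, after which
    concentrations are back-computed through a drawn urinary creatinine
    (uP = uPCR x uCr, uAlb = uACR x uCr / 100) and censored below the
    detection limits.  Serum creatinine is made consistent with the
    assigned GFR category through the eGFR equation.
    """
    ss = np.random.SeedSequence(truth.seed)
    children = ss.spawn(truth.n_patients)
    g = _upcr_quantile_transform(truth)
    sd_between = float(np.sqrt(truth.upcr_icc))
    sd_within = float(np.sqrt(1.0 - truth.upcr_icc))
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        diabetic = bool(rng.random() < truth.diabetes_fraction)
        curve = truth.curve_population[diabetic]
        sex = "M" if rng.random() < _MALE_FRACTION[diabetic] else "F"
        age = round(_truncated_normal(rng, truth.age_mean, truth.age_sd,
                                      *truth.age_bounds))
        mix = _GFR_MIX[diabetic]
        cats = sorted(mix)
        cat = rng.choice(cats, p=[mix[c] for c in cats])
        egfr_target = rng.uniform(*_GFR_RANGES[cat])

        z_i = rng.normal(0.0, sd_between)
        b_i = rng.normal(0.0, truth.uacr_patient_sd)

        days = [0]
        for mean, sd in zip(truth.visit_interval_means, truth.visit_interval_sds):
            gap = max(truth.min_interval_days, rng.normal(mean, sd))
            days.append(days[-1] + int(round(gap)))

        for day in days:
            ln_upcr = float(g(z_i + rng.normal(0.0, sd_within)))
            # the coupling of uACR to uPCR tightens once proteinuria is
            # dominated by albumin (uPCR above ~0.2 g/gCr), so the
            # residual spread tapers toward a floor at high uPCR
            t0, t1 = np.log(truth.uacr_taper_start), np.log(truth.uacr_taper_end)
            if ln_upcr <= t0:
                scale = 1.0
            else:
                frac = (ln_upcr - t0) / (t1 - t0)
                scale = max(truth.uacr_taper_floor,
                            1.0 - (1.0 - truth.uacr_taper_floor) * frac)
            ln_uacr = (_predict_ln_extrapolated(curve, ln_upcr)
                       + scale * (b_i + rng.normal(0.0, truth.uacr_visit_sd)))
            upcr_g = float(np.exp(ln_upcr)) / 1000.0      # g/gCr
            uacr = float(np.exp(ln_uacr))                 # mg/gCr
            ucr = float(np.exp(rng.normal(truth.ln_ucr_mean, truth.ln_ucr_sd)))
            up = upcr_g * ucr                             # mg/dl
            ualb = uacr * ucr / 100.0                     # mg/l
            up_cens = up < truth.up_detection_limit
            ualb_cens = ualb < truth.ualb_detection_limit
            egfr = egfr_target * float(
                np.exp(rng.normal(0.0, truth.egfr_visit_cv)))
            scr = _serum_cr_for_egfr(
                egfr, age, "male" if sex == "M" else "female")
            rows.append({
                "patient_id": f"P{i:05d}", "age": age, "sex": sex,
                "diabetes": int(diabetic), "day": day,
                "serum_cr_mgdl": round(scr, 3),
                "up_mgdl": 0.0 if up_cens else round(up, 2),
                "ualb_mgl": 0.0 if ualb_cens else round(ualb, 2),
                "ucr_mgdl": round(ucr, 2),
                "up_censored": int(up_cens),
                "ualb_censored": int(ualb_cens),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@dataclass
class StabilityTruth:
    """Ground-truth parameters of the same-sample stability substudy.

    Measurement o of a sample with true concentration T is
    (T + a_c) * exp(shift_c + e_o): e_o is occasion-specific assay noise
    and shift_c a multiplicative storage perturbation shared within a
    condition (the two post-freeze-thaw measurements share one
    perturbation, which is why they agree better with each other than
    with the fresh value).  For urinary protein, storage additionally
    perturbs the concentration by an *additive* trace-level term a_c of
    sd ``up_storage_additive_sd`` mg/dl: an absolute perturbation of this
    size is negligible at high protein but dominates below ~3 mg/dl,
    which is what degrades the correlation of stored trace-protein
    measurements while leaving higher concentrations reproducible.
    """

    n_samples: int = 88
    ln_up_mean: float = float(np.log(5.5))   # ln(mg/dl)
    ln_up_sd: float = 1.3
    ln_ucr_mean: float = float(np.log(65.0))
    ln_ucr_sd: float = 0.5
    uacr_residual_sd: float = 0.5            # around the median curve
    age_mean: float = 73.1
    age_sd: float = 12.7
    assay_cv: dict = field(default_factory=lambda: {
        "up": 0.08, "ualb": 0.04, "ucr": 0.015})
    refrigeration_sd: dict = field(default_factory=lambda: {
        "up": 0.15, "ualb": 0.10, "ucr": 0.010})
    freeze_thaw_sd: dict = field(default_factory=lambda: {
        "up": 0.20, "ualb": 0.30, "ucr": 0.015})
    up_storage_additive_sd: float = 0.8      # mg/dl
    concentration_floor: float = 0.05        # mg/dl, after additive noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for d in (self.assay_cv, self.refrigeration_sd, self.freeze_thaw_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("noise scales must be non-negative")


#: Substudy GFR mix (2, 18, 29, 29, 10 of 88).
_STAB_GFR_MIX = {"G1": 2 / 88, "G2": 18 / 88, "G3a": 29 / 88,
                 "G3b": 29 / 88, "G4": 10 / 88}


def generate_stability_study(truth: StabilityTruth,
                             curve: SplineModel | None = None
                             ) -> list[StabilitySample]:
    """Generate the four-occasion stability samples.

    True uACR follows the published overall median curve at the sample's
    true uPCR plus lognormal residual; urinary albumin is back-computed
    through the drawn urinary creatinine.
    """
    if curve is None:
        curve = load_published_model("all")
    ss = np.random.SeedSequence(truth.seed)
    samples = []
    for i, child in enumerate(ss.spawn(truth.n_samples)):
        rng = np.random.default_rng(child)
        up_true = float(np.exp(rng.normal(truth.ln_up_mean, truth.ln_up_sd)))
        ucr_true = float(np.exp(rng.normal(truth.ln_ucr_mean, truth.ln_ucr_sd)))
        upcr_mg = up_true / ucr_true * 1000.0
        ln_uacr = (_predict_ln_extrapolated(curve, float(np.log(upcr_mg)))
                   + rng.normal(0.0, truth.uacr_residual_sd))
        ualb_true = float(np.exp(ln_uacr)) * ucr_true / 100.0

        age = max(30.0, rng.normal(truth.age_mean, truth.age_sd))
        sex = "male" if rng.random() < 48 / 88 else "female"
        cats = sorted(_STAB_GFR_MIX)
        cat = rng.choice(cats, p=[_STAB_GFR_MIX[c] for c in cats])
        scr = _serum_cr_for_egfr(rng.uniform(*_GFR_RANGES[cat]), age, sex)

        meas = {}
        for analyte, true in [("up", up_true), ("ualb", ualb_true),
                              ("ucr", ucr_true)]:
            refrig = rng.normal(0.0, truth.refrigeration_sd[analyte])
            freeze = rng.normal(0.0, truth.freeze_thaw_sd[analyte])
            assay = rng.normal(0.0, truth.assay_cv[analyte], size=4)
            shifts = np.array([0.0, refrig, freeze, freeze])
            if analyte == "up":
                refrig_add = rng.normal(0.0, truth.up_storage_additive_sd)
                freeze_add = rng.normal(0.0, truth.up_storage_additive_sd)
                # occasions 3 and 4 re-measure the same thawed specimen
                adds = np.array([0.0, refrig_add, freeze_add, freeze_add])
            else:
                adds = np.zeros(4)
            meas[analyte] = tuple(
                round(float(max(truth.concentration_floor, true + adds[o])
                            * np.exp(shifts[o] + assay[o])), 3)
                for o in range(4)
            )
        samples.append(StabilitySample(
            sample_id=f"S{i:04d}", serum_cr=round(scr, 3),
            up=meas["up"], ualb=meas["ualb"], ucr=meas["ucr"],
        ))
    return samples
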