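"""Patient-level data model for spot-urine proteinuria/albuminuria studies.

Holds the unit-correct derivation of the urinary protein-to-creatinine
ratio (uPCR, g/gCr) and albumin-to-creatinine ratio (uACR, mg/gCr) from
assay concentrations, KDIGO GFR staging from estimated GFR, the
repeated-measurement albuminuria classification rules, and cohort
eligibility filtering.

Units follow clinical laboratory convention throughout: urinary protein
and creatinine in mg/dl, urinary albumin in mg/l, serum creatinine in
mg/dl, eGFR in ml/min/1.73 m^2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AlbuminuriaCategory",
    "GFRCategory",
    "InvalidMeasurementError",
    "PatientRecord",
    "UrineMeasurement",
    "apply_eligibility",
    "classify_albuminuria_measurement",
    "classify_albuminuria_patient",
    "compute_egfr",
    "derive_ratios",
    "gfr_category_from_series",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_exclusion_report",
]

#: Columns of the one-row-per-visit cohort CSV.
COHORT_COLUMNS = [
    "patient_id", "age", "sex", "diabetes", "day", "serum_cr_mgdl",
    "up_mgdl", "ualb_mgl", "ucr_mgdl", "up_censored", "ualb_censored",
]


class InvalidMeasurementError(ValueError):
    """Raised when a urine assay triplet cannot yield valid ratios."""


class GFRCategory(enum.Enum):
    """KDIGO GFR stage, determined solely by eGFR."""

    G1 = "G1"
    G2 = "G2"
    G3a = "G3a"
    G3b = "G3b"
    G4 = "G4"
    G5 = "G5"


class AlbuminuriaCategory(enum.Enum):
    """Albuminuria stage from uACR (mg/gCr): <30, 30-299, >=300."""

    NORMO = "normo"
    MICRO = "micro"
    MACRO = "macro"


@dataclass(frozen=True)
class UrineMeasurement:
    """One spot-urine assay triplet with derived ratios.

    Censored (below-detection) concentrations are stored as numeric 0
    with the corresponding flag set; derived ratios for censored inputs
    are likewise 0, mirroring how undetected uACR/uPCR are tabulated.
    """

    day_index: int
    uP: float          # urinary protein, mg/dl
    uAlb: float        # urinary albumin, mg/l
    uCr: float         # urinary creatinine, mg/dl
    uP_censored: bool = False
    uAlb_censored: bool = False
    uPCR: float | None = None   # g/gCr
    uACR: float | None = None   # mg/gCr


@dataclass
class PatientRecord:
    """Demographics plus the urine-visit series for one patient."""

    id: str
    age: float
    sex: str                     # "male" | "female" (accepts "M"/"F")
    diabetes: bool
    serum_cr: list[tuple[int, float]] = field(default_factory=list)
    egfr_series: list[tuple[int, float]] = field(default_factory=list)
    visits: list[UrineMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        sex = self.sex.lower()
        self.sex = {"m": "male", "f": "female"}.get(sex, sex)
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        self.visits = sorted(self.visits, key=lambda m: m.day_index)

    @property
    def uacr_values(self) -> list[float]:
        return [m.uACR for m in self.visits if m.uACR is not None]

    @property
    def upcr_values(self) -> list[float]:
        return [m.uPCR for m in self.visits if m.uPCR is not None]


def derive_ratios(m: UrineMeasurement) -> UrineMeasurement:
    """Fill uPCR (g/gCr) and uACR (mg/gCr) from assay concentrations.

    uPCR = uP / uCr (mg/dl over mg/dl is mg/mg, i.e. g/gCr).
    uACR = uAlb * 100 / uCr (uAlb in mg/l is 0.1 mg/dl; dividing by uCr in
    mg/dl gives g/gCr, times 1000 -> mg/gCr, net factor 100).

    Censored inputs yield a ratio of 0 with the censoring flag preserved.
    """
    if m.uCr <= 0:
        raise InvalidMeasurementError(
            f"urinary creatinine must be positive to derive ratios, got {m.uCr}"
        )
    if m.uP < 0 or m.uAlb < 0:
        raise InvalidMeasurementError("concentrations must be non-negative")
    upcr = 0.0 if m.uP_censored else m.uP / m.uCr
    uacr = 0.0 if m.uAlb_censored else m.uAlb * 100.0 / m.uCr
    return replace(m, uPCR=upcr, uACR=uacr)


def compute_egfr(
    serum_cr: float,
    age: float,
    sex: str,
    *,
    coefficient: float = 194.0,
    cr_exponent: float = -1.094,
    age_exponent: float = -0.287,
    female_factor: float = 0.739,
) -> float:
    """Estimated GFR (ml/min/1.73 m^2) from serum creatinine, age and sex.

    Defaults implement the Japanese Society of Nephrology equation
    eGFR = 194 * sCr^-1.094 * age^-0.287 (x 0.739 if female); the
    coefficients are keyword-pluggable so another creatinine equation can
    be substituted.
    """
    if serum_cr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_cr}")
    if age < 18:
        raise ValueError("equation applies to adults (age >= 18)")
    sex = {"m": "male", "f": "female"}.get(sex.lower(), sex.lower())
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    egfr = coefficient * serum_cr**cr_exponent * age**age_exponent
    if sex == "female":
        egfr *= female_factor
    return egfr


# KDIGO stage lower bounds (half-open on the right except G1).
_GFR_STAGES = [
    (90.0, GFRCategory.G1),
    (60.0, GFRCategory.G2),
    (45.0, GFRCategory.G3a),
    (30.0, GFRCategory.G3b),
    (15.0, GFRCategory.G4),
    (0.0, GFRCategory.G5),
]


def gfr_category_from_series(egfr_series) -> GFRCategory:
    """GFR category from the mean of the available eGFR values.

    The average eGFR over the observation period determines the stage;
    boundaries are half-open with the lower edge inclusive (e.g. exactly
    60 is G2, exactly 45 is G3a).
    """
    values = [v[1] if isinstance(v, tuple) else v for v in egfr_series]
    if len(values) == 0:
        raise ValueError("empty eGFR series")
    mean = float(np.mean(values))
    for lower, cat in _GFR_STAGES:
        if mean >= lower:
            return cat
    raise AssertionError("unreachable")


def classify_albuminuria_measurement(uacr: float) -> AlbuminuriaCategory:
    """Stage a single uACR value: <30 normo, 30-299 micro, >=300 macro."""
    if uacr < 0:
        raise ValueError(f"uACR must be non-negative, got {uacr}")
    if uacr < 30:
        return AlbuminuriaCategory.NORMO
    if uacr < 300:
        return AlbuminuriaCategory.MICRO
    return AlbuminuriaCategory.MACRO


def classify_albuminuria_patient(uacr_triplet) -> AlbuminuriaCategory:
    """Patient-level albuminuria category from three repeated uACR values.

    A category reached on at least two of the three measurements wins.
    If normo-, micro- and macroalbuminuric values each occur exactly once,
    the patient is classified as microalbuminuric (the intermediate
    category), per the study's repeated-measurement rule.
    """
    values = list(uacr_triplet)
    if len(values) != 3:
        raise ValueError(f"exactly 3 uACR values required, got {len(values)}")
    cats = [classify_albuminuria_measurement(v) for v in values]
    for cat in AlbuminuriaCategory:
        if cats.count(cat) >= 2:
            return cat
    return AlbuminuriaCategory.MICRO


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def apply_eligibility(
    cohort: list[PatientRecord],
    *,
    max_first_upcr: float = 0.5,
    min_first_egfr: float = 15.0,
    egfr_drop_fraction: float = 0.30,
    egfr_drop_window_days: int = 92,
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Apply the cohort entry criteria and the rapid-decline exclusion.

    Kept patients have first-visit uPCR < 0.5 g/gCr and first eGFR
    >= 15 ml/min/1.73 m^2, and no pair of eGFR measurements <= 92 days
    apart with a drop of >= 30% (a drop of exactly 30% excludes).
    A later uPCR rising to >= 0.5 g/gCr never excludes. Patients missing
    first-visit data are excluded with reason ``incomplete``.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for p in cohort:
        if not p.visits or not p.egfr_series or p.visits[0].uPCR is None:
            excluded.append(Exclusion(p.id, "incomplete"))
            continue
        if p.visits[0].uPCR >= max_first_upcr:
            excluded.append(Exclusion(p.id, "first_upcr_ge_0.5"))
            continue
        series = sorted(p.egfr_series)
        if series[0][1] < min_first_egfr:
            excluded.append(Exclusion(p.id, "first_egfr_lt_15"))
            continue
        drop = False
        for i in range(len(series)):
            for j in range(i + 1, len(series)):
                di, ei = series[i]
                dj, ej = series[j]
                if dj - di <= egfr_drop_window_days and ei > 0:
                    if (ei - ej) / ei >= egfr_drop_fraction:
                        drop = True
        if drop:
            excluded.append(Exclusion(p.id, "egfr_drop_ge_30pct"))
        else:
            kept.append(p)
    return kept, excluded


# ---------------------------------------------------------------------------
# CSV interface (one row per patient-visit)

def read_cohort_csv(path) -> list[PatientRecord]:
    """Read the cohort CSV into PatientRecords with derived ratios and eGFR.

    Expects columns: patient_id, age, sex{M,F}, diabetes{0,1}, day,
    serum_cr_mgdl, up_mgdl, ualb_mgl, ucr_mgdl, up_censored{0,1},
    ualb_censored{0,1}. eGFR is computed per row from serum creatinine.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns: {sorted(missing)}")
    return cohort_from_frame(df)


def cohort_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Build PatientRecords from a one-row-per-visit DataFrame."""
    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        visits = []
        serum, egfr = [], []
        for _, row in grp.iterrows():
            m = UrineMeasurement(
                day_index=int(row["day"]),
                uP=float(row["up_mgdl"]),
                uAlb=float(row["ualb_mgl"]),
                uCr=float(row["ucr_mgdl"]),
                uP_censored=bool(row["up_censored"]),
                uAlb_censored=bool(row["ualb_censored"]),
            )
            visits.append(derive_ratios(m))
            scr = float(row["serum_cr_mgdl"])
            serum.append((int(row["day"]), scr))
            egfr.append(
                (int(row["day"]),
                 compute_egfr(scr, float(first["age"]), str(first["sex"])))
            )
        patients.append(
            PatientRecord(
                id=str(pid),
                age=float(first["age"]),
                sex=str(first["sex"]),
                diabetes=bool(first["diabetes"]),
                serum_cr=serum,
                egfr_series=egfr,
                visits=visits,
            )
        )
    return patients


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        scr = dict(p.serum_cr)
        for m in p.visits:
            rows.append({
                "patient_id": p.id,
                "age": p.age,
                "sex": "M" if p.sex == "male" else "F",
                "diabetes": int(p.diabetes),
                "day": m.day_index,
                "serum_cr_mgdl": scr.get(m.day_index, np.nan),
                "up_mgdl": m.uP,
                "ualb_mgl": m.uAlb,
                "ucr_mgdl": m.uCr,
                "up_censored": int(m.uP_censored),
                "ualb_censored": int(m.uAlb_censored),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(cohort: list[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def write_exclusion_report(excluded: list[Exclusion], path) -> None:
    pd.DataFrame(
        [{"patient_id": e.patient_id, "reason": e.reason} for e in excluded],
        columns=["patient_id", "reason"],
    ).to_csv(path, index=False)
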