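"""Cohort-level discrimination analyses.

Builds single and summed uPCR discriminators of patient-level
microalbuminuria, per-measurement uACR-threshold ROC tables, subgroup
cutoffs, uPCR x uACR contingency tables by GFR stratum, and
visit-to-visit delta regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    AlbuminuriaCategory,
    PatientRecord,
    classify_albuminuria_patient,
    gfr_category_from_series,
)
from .roc import paired_auc_test, roc_points, youden_cutoff

__all__ = [
    "DiscriminatorSet",
    "build_discriminators",
    "delta_regression",
    "distribution_crosstab",
    "false_positive_audit",
    "microalbuminuria_discrimination",
    "pooled_measurements",
    "subgroup_cutoffs",
    "uacr_threshold_table",
]

#: Discriminator column order: three single uPCRs, pairwise sums, the
#: triple sum, then the three single uACRs.
DISCRIMINATORS = [
    "uPCR1", "uPCR2", "uPCR3",
    "uPCR1.2", "uPCR2.3", "uPCR1.3", "uPCR1.2.3",
    "uACR1", "uACR2", "uACR3",
]

DEFAULT_UACR_THRESHOLDS = tuple(range(10, 151, 10)) + (300,)
DEFAULT_UACR_BANDS = (0.0, 10.0, 20.0, 30.0, 60.0, 100.0, 150.0, 200.0, 300.0, np.inf)
DEFAULT_UPCR_BANDS = (0.0, 0.09, 0.15, 0.50, np.inf)


@dataclass
class DiscriminatorSet:
    """Per-patient discriminator table with the patient-level label.

    ``frame`` has one row per patient with columns ``DISCRIMINATORS``
    plus id/age/sex/diabetes/gfr_group and the boolean ``positive`` label
    (micro- or macroalbuminuria vs normoalbuminuria).  ``skipped`` lists
    ids of patients without three classified visits.
    """

    frame: pd.DataFrame
    skipped: list[str]


def build_discriminators(cohort: list[PatientRecord],
                         gfr_split: float = 45.0) -> DiscriminatorSet:
    """Assemble the single/summed uPCR and uACR discriminators per patient.

    The patient label is positive when the repeated-measurement rule
    classifies the uACR triplet as micro- or macroalbuminuria.
    ``gfr_split`` partitions patients into an early (mean eGFR >= split,
    i.e. G1-3a for 45) and a late (G3b-4) GFR group.
    """
    rows, skipped = [], []
    for p in cohort:
        if len(p.visits) < 3:
            skipped.append(p.id)
            continue
        u = p.upcr_values[:3]
        a = p.uacr_values[:3]
        cat = classify_albuminuria_patient(a)
        mean_egfr = float(np.mean([v for _, v in p.egfr_series]))
        rows.append({
            "id": p.id, "age": p.age, "sex": p.sex, "diabetes": p.diabetes,
            "gfr_category": gfr_category_from_series(p.egfr_series).value,
            "gfr_group": "early" if mean_egfr >= gfr_split else "late",
            "uPCR1": u[0], "uPCR2": u[1], "uPCR3": u[2],
            "uPCR1.2": u[0] + u[1], "uPCR2.3": u[1] + u[2],
            "uPCR1.3": u[0] + u[2], "uPCR1.2.3": u[0] + u[1] + u[2],
            "uACR1": a[0], "uACR2": a[1], "uACR3": a[2],
            "category": cat.value,
            "positive": cat is not AlbuminuriaCategory.NORMO,
        })
    return DiscriminatorSet(frame=pd.DataFrame(rows), skipped=skipped)


def pooled_measurements(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Pool every visit as an independent (uPCR, uACR) record.

    Each of the up-to-three visits contributes one row (no within-patient
    clustering correction), with patient covariates repeated.
    """
    rows = []
    for p in cohort:
        gfr = gfr_category_from_series(p.egfr_series).value if p.egfr_series else None
        mean_egfr = (float(np.mean([v for _, v in p.egfr_series]))
                     if p.egfr_series else np.nan)
        for m in p.visits:
            rows.append({
                "id": p.id, "age": p.age, "sex": p.sex, "diabetes": p.diabetes,
                "gfr_category": gfr, "mean_egfr": mean_egfr,
                "upcr": m.uPCR, "uacr": m.uACR,
            })
    return pd.DataFrame(rows)


def uacr_threshold_table(records: pd.DataFrame,
                         thresholds=DEFAULT_UACR_THRESHOLDS) -> pd.DataFrame:
    """Per-threshold discrimination of uACR >= X by uPCR on pooled records.

    One ROC + Youden cutoff per threshold X; rows where only one class is
    present are flagged (``degenerate``) rather than computed.
    """
    out = []
    for x in thresholds:
        labels = records["uacr"].to_numpy() >= x
        row = {"uacr_threshold": x, "n_ge_x": int(labels.sum())}
        if labels.all() or not labels.any():
            row.update({"degenerate": True})
        else:
            roc = roc_points(records["upcr"].to_numpy(), labels)
            co = youden_cutoff(roc)
            row.update({
                "degenerate": False,
                "auc": roc.auc, "auc_se": roc.auc_se,
                "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "p": roc.p_value,
                "cutoff": co.cutoff, "sensitivity": co.sensitivity,
                "specificity": co.specificity, "youden": co.youden,
            })
        out.append(row)
    return pd.DataFrame(out)


def microalbuminuria_discrimination(ds: DiscriminatorSet):
    """Evaluate all ten discriminators of patient-level microalbuminuria.

    Returns (table, pairwise) where ``table`` has one row per
    discriminator (AUC, SE, p vs 0.5, Youden cutoff, Se, Sp) and
    ``pairwise`` holds the DeLong comparisons for every discriminator
    pair (delta AUC, z, two-sided p).
    """
    df = ds.frame
    labels = df["positive"].to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("both albuminuria classes must be present")
    rows = []
    for name in DISCRIMINATORS:
        scores = df[name].to_numpy()
        roc = roc_points(scores, labels)
        co = youden_cutoff(roc)
        rows.append({
            "discriminator": name, "auc": roc.auc, "auc_se": roc.auc_se,
            "p": roc.p_value, "cutoff": co.cutoff,
            "sensitivity": co.sensitivity, "specificity": co.specificity,
            "youden": co.youden,
        })
    table = pd.DataFrame(rows).set_index("discriminator")
    pairs = []
    for i, a in enumerate(DISCRIMINATORS):
        for b in DISCRIMINATORS[i + 1:]:
            delta, se, z, p = paired_auc_test(
                df[a].to_numpy(), df[b].to_numpy(), labels)
            pairs.append({"a": a, "b": b, "delta_auc": delta,
                          "se": se, "z": z, "p": p})
    return table, pd.DataFrame(pairs)


def _age_band(age: float) -> str:
    if age < 65:
        return "<65"
    if age < 80:
        return "65-<80"
    return ">=80"


def subgroup_cutoffs(ds_frame: pd.DataFrame, score: str, label: str,
                     axis: str) -> pd.DataFrame:
    """Youden cutoffs of ``score`` for ``label`` within subgroups of ``axis``.

    ``axis`` is one of ``age`` ([18,65), [65,80), [80,inf)), ``sex``,
    ``gfr`` (early G1-3a vs late G3b-4) or ``diabetes``; subgroups
    partition the rows.  Single-class subgroups are flagged.
    """
    df = ds_frame
    if axis == "age":
        groups = df.groupby(df["age"].map(_age_band))
    elif axis == "sex":
        groups = df.groupby("sex")
    elif axis == "gfr":
        groups = df.groupby("gfr_group")
    elif axis == "diabetes":
        groups = df.groupby("diabetes")
    else:
        raise ValueError(f"unknown subgroup axis {axis!r}")
    out = []
    for key, grp in groups:
        labels = grp[label].to_numpy().astype(bool)
        row = {"axis": axis, "subgroup": str(key), "n": len(grp),
               "n_pos": int(labels.sum())}
        if labels.all() or not labels.any():
            row["degenerate"] = True
        else:
            roc = roc_points(grp[score].to_numpy(), labels)
            co = youden_cutoff(roc)
            row.update({
                "degenerate": False, "auc": roc.auc, "auc_se": roc.auc_se,
                "p": roc.p_value, "cutoff": co.cutoff,
                "sensitivity": co.sensitivity, "specificity": co.specificity,
            })
        out.append(row)
    return pd.DataFrame(out)


def distribution_crosstab(records: pd.DataFrame,
                          upcr_bands=DEFAULT_UPCR_BANDS,
                          uacr_bands=DEFAULT_UACR_BANDS) -> pd.DataFrame:
    """uPCR-band x uACR-band contingency counts per GFR stratum.

    Bands are half-open [lo, hi).  Records must carry ``gfr_category``;
    strata are pooled into early (G1-3a) vs late (G3b+).
    """
    df = records.copy()
    early = {"G1", "G2", "G3a"}
    df["gfr_stratum"] = np.where(df["gfr_category"].isin(early), "G1-3a", "G3b-4")
    df["upcr_band"] = pd.cut(df["upcr"], bins=list(upcr_bands), right=False)
    df["uacr_band"] = pd.cut(df["uacr"], bins=list(uacr_bands), right=False)
    tab = (
        df.groupby(["gfr_stratum", "uacr_band", "upcr_band"], observed=False)
        .size()
        .unstack("upcr_band")
    )
    return tab


def false_positive_audit(records: pd.DataFrame, cutoff: float,
                         uacr_positive: float = 30.0,
                         uacr_floor: float = 10.0) -> dict:
    """Among uPCR >= cutoff but uACR < 30 records, the share with uACR >= 10.

    Quantifies how many "false positives" of a proteinuria cutoff are in
    fact low-grade albuminuria rather than true normality.
    """
    fp = records[(records["upcr"] >= cutoff) & (records["uacr"] < uacr_positive)]
    n_fp = len(fp)
    n_floor = int((fp["uacr"] >= uacr_floor).sum())
    return {
        "n_false_positive": n_fp,
        "n_uacr_ge_floor": n_floor,
        "fraction": n_floor / n_fp if n_fp else np.nan,
    }


def delta_regression(ds: DiscriminatorSet, split: float = 0.15) -> pd.DataFrame:
    """Simple regression of visit-to-visit uACR change on uPCR change.

    Patients are split by first uPCR </>= ``split`` g/gCr; within each
    split, delta = visit2 - visit1 and visit3 - visit2 pairs are fit by
    OLS (slope, intercept), with the Pearson correlation and its
    two-sided p.  A split with fewer than 3 patients contributes no rows;
    if no split is estimable an error is raised.
    """
    df = ds.frame
    out = []
    for name, mask in [(f"first_upcr<{split}", df["uPCR1"] < split),
                       (f"first_upcr>={split}", df["uPCR1"] >= split)]:
        sub = df[mask]
        if len(sub) < 3:
            continue
        for pair, (u_hi, u_lo, a_hi, a_lo) in {
            "2-1": ("uPCR2", "uPCR1", "uACR2", "uACR1"),
            "3-2": ("uPCR3", "uPCR2", "uACR3", "uACR2"),
        }.items():
            dx = (sub[u_hi] - sub[u_lo]).to_numpy()
            dy = (sub[a_hi] - sub[a_lo]).to_numpy()
            if np.allclose(dx, dx[0]):
                raise ValueError(f"zero variance in delta uPCR for {name}, {pair}")
            res = stats.linregress(dx, dy)
            out.append({
                "split": name, "pair": pair, "n": len(sub),
                "slope": res.slope, "intercept": res.intercept,
                "r": res.rvalue, "p": res.pvalue,
            })
    if not out:
        raise ValueError("no split has the 3 patients needed for regression")
    return pd.DataFrame(out)
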