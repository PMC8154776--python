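"""Intra/interday same-sample stability substudy.

Each urine sample is measured four times: fresh (occasion 1), after 3-4 h
refrigerated (occasion 2), and twice consecutively after 3-4 days of
freezing and thawing (occasions 3 and 4).  Agreement between any two
occasions is summarized per concentration stratum by the OLS regression
line of the later on the earlier measurement, the Pearson correlation,
and the median (IQR) of the bias (later minus earlier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roc import paired_auc_test, roc_points, youden_cutoff

__all__ = [
    "CONDITIONS",
    "StabilityPairSummary",
    "StabilitySample",
    "pair_agreement",
    "read_stability_csv",
    "stability_cutoffs",
    "stability_to_frame",
    "stratify_pairs",
]

#: Occasion -> storage condition.
CONDITIONS = {1: "fresh", 2: "refrigerated_3-4h",
              3: "freezethaw_rep1", 4: "freezethaw_rep2"}

#: Fixed stratum boundaries per analyte (half-open [lo, hi) bands on the
#: mean of the two compared measurements), as used in the substudy.
STRATUM_EDGES = {
    "up": (3.0, 8.0),       # mg/dl
    "ualb": (15.0, 40.0),   # mg/l
    "ucr": (50.0, 90.0),    # mg/dl
    "upcr": (0.15,),        # g/gCr
    "uacr": (0.15,),        # stratified by the paired mean uPCR
}

STABILITY_COLUMNS = [
    "sample_id", "occasion", "condition",
    "up_mgdl", "ualb_mgl", "ucr_mgdl", "serum_cr_mgdl",
]


@dataclass
class StabilitySample:
    """One sample's four assay triplets plus the day-0 serum creatinine."""

    sample_id: str
    serum_cr: float                       # mg/dl, day 0
    up: tuple[float, float, float, float]     # mg/dl per occasion
    ualb: tuple[float, float, float, float]   # mg/l
    ucr: tuple[float, float, float, float]    # mg/dl

    def upcr(self, occ: int) -> float:
        return self.up[occ - 1] / self.ucr[occ - 1]

    def uacr(self, occ: int) -> float:
        return self.ualb[occ - 1] * 100.0 / self.ucr[occ - 1]

    def ucr_scr(self, occ: int) -> float:
        """Urine-to-serum creatinine ratio (dimensionless urine concentration
        index), always against the single day-0 serum creatinine."""
        return self.ucr[occ - 1] / self.serum_cr


@dataclass
class StabilityPairSummary:
    analyte: str
    pair: str                 # e.g. "1-2"
    stratum: str
    n: int
    slope: float              # later on earlier
    intercept: float
    r: float
    p: float
    bias_median: float        # later - earlier
    bias_q1: float
    bias_q3: float


def _analyte_values(s: StabilitySample, analyte: str, occ: int) -> float:
    if analyte == "up":
        return s.up[occ - 1]
    if analyte == "ualb":
        return s.ualb[occ - 1]
    if analyte == "ucr":
        return s.ucr[occ - 1]
    if analyte == "upcr":
        return s.upcr(occ)
    if analyte == "uacr":
        return s.uacr(occ)
    raise ValueError(f"unknown analyte {analyte!r}")


def _stratum_label(analyte: str, mean: float) -> str:
    edges = STRATUM_EDGES[analyte]
    if len(edges) == 1:
        return f"<{edges[0]}" if mean < edges[0] else f">={edges[0]}"
    lo, hi = edges
    if mean < lo:
        return f"<{lo}"
    if mean < hi:
        return f"{lo} to <{hi}"
    return f">={hi}"


def stratify_pairs(samples: list[StabilitySample], analyte: str,
                   pair: tuple[int, int]) -> dict[str, list[tuple[float, float]]]:
    """Group (earlier, later) measurement pairs into concentration strata.

    The stratum is assigned from the mean of the two compared
    measurements; uPCR and uACR pairs are both stratified by the mean of
    the two uPCR values (the study's dilution-corrected split at
    0.15 g/gCr), the concentration analytes by their own fixed bands.
    """
    earlier, later = pair
    out: dict[str, list[tuple[float, float]]] = {}
    for s in samples:
        x = _analyte_values(s, analyte, earlier)
        y = _analyte_values(s, analyte, later)
        if analyte in ("upcr", "uacr"):
            basis = (s.upcr(earlier) + s.upcr(later)) / 2.0
        else:
            basis = (x + y) / 2.0
        label = _stratum_label(analyte, basis)
        out.setdefault(label, []).append((x, y))
    return out


def pair_agreement(pairs, analyte: str = "", pair_label: str = "",
                   stratum: str = "") -> StabilityPairSummary:
    """Agreement summary for one stratum of repeated-measurement pairs.

    OLS of the later on the earlier measurement, Pearson r with its
    two-sided p, and the median/IQR of (later - earlier).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (earlier, later) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("earlier measurements are all equal; "
                         "regression is degenerate")
    res = stats.linregress(x, y)
    bias = y - x
    q1, med, q3 = np.percentile(bias, [25, 50, 75], method="linear")
    return StabilityPairSummary(
        analyte=analyte, pair=pair_label, stratum=stratum, n=len(x),
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue),
        bias_median=float(med), bias_q1=float(q1), bias_q3=float(q3),
    )


def agreement_table(samples: list[StabilitySample], analyte: str,
                    pairs=((1, 2), (3, 4), (1, 3), (1, 4), (2, 3), (2, 4)),
                    min_n: int = 3) -> pd.DataFrame:
    """All stratified agreement summaries for one analyte."""
    rows = []
    for pair in pairs:
        label = f"{pair[0]}-{pair[1]}"
        for stratum, pts in sorted(stratify_pairs(samples, analyte, pair).items()):
            if len(pts) < min_n:
                continue
            s = pair_agreement(pts, analyte, label, stratum)
            rows.append(vars(s))
    return pd.DataFrame(rows)


def stability_cutoffs(samples: list[StabilitySample],
                      uacr_threshold: float = 30.0) -> pd.DataFrame:
    """Per-occasion Youden cutoffs of uP concentration and uPCR.

    For each of the four occasions: the cutoff of the raw urinary protein
    concentration (mg/dl) and of uPCR (g/gCr) discriminating
    same-occasion uACR >= 30 mg/gCr, with the paired DeLong comparison of
    the two score types, plus the uPCR cutoff for the mean of the four
    uACR values >= 30.  Single-class occasions are flagged.
    """
    mean4 = np.array([np.mean([s.uacr(o) for o in range(1, 5)]) for s in samples])
    rows = []
    for occ in range(1, 5):
        up = np.array([s.up[occ - 1] for s in samples])
        upcr = np.array([s.upcr(occ) for s in samples])
        uacr = np.array([s.uacr(occ) for s in samples])
        for target_name, labels in [("same_occasion", uacr >= uacr_threshold),
                                    ("mean_of_4", mean4 >= uacr_threshold)]:
            row = {"occasion": occ, "condition": CONDITIONS[occ],
                   "target": target_name, "n_pos": int(labels.sum())}
            if labels.all() or not labels.any():
                row["degenerate"] = True
                rows.append(row)
                continue
            row["degenerate"] = False
            roc_pcr = roc_points(upcr, labels)
            co_pcr = youden_cutoff(roc_pcr)
            row.update({
                "upcr_auc": roc_pcr.auc, "upcr_auc_se": roc_pcr.auc_se,
                "upcr_cutoff": co_pcr.cutoff,
                "upcr_sensitivity": co_pcr.sensitivity,
                "upcr_specificity": co_pcr.specificity,
            })
            if target_name == "same_occasion":
                roc_up = roc_points(up, labels)
                co_up = youden_cutoff(roc_up)
                delta, se, z, p = paired_auc_test(upcr, up, labels)
                row.update({
                    "up_auc": roc_up.auc, "up_auc_se": roc_up.auc_se,
                    "up_cutoff": co_up.cutoff,
                    "up_sensitivity": co_up.sensitivity,
                    "up_specificity": co_up.specificity,
                    "auc_diff_upcr_minus_up": delta,
                    "auc_diff_p": p,
                })
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interface

def read_stability_csv(path) -> list[StabilitySample]:
    """Read the long-format stability CSV (one row per sample-occasion)."""
    df = pd.read_csv(path)
    missing = set(STABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stability CSV {path} missing columns: {sorted(missing)}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("occasion")
        if list(grp["occasion"]) != [1, 2, 3, 4]:
            raise ValueError(f"sample {sid} must have occasions 1..4 exactly")
        samples.append(StabilitySample(
            sample_id=str(sid),
            serum_cr=float(grp["serum_cr_mgdl"].iloc[0]),
            up=tuple(grp["up_mgdl"].astype(float)),
            ualb=tuple(grp["ualb_mgl"].astype(float)),
            ucr=tuple(grp["ucr_mgdl"].astype(float)),
        ))
    return samples


def stability_to_frame(samples: list[StabilitySample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for occ in range(1, 5):
            rows.append({
                "sample_id": s.sample_id, "occasion": occ,
                "condition": CONDITIONS[occ],
                "up_mgdl": s.up[occ - 1], "ualb_mgl": s.ualb[occ - 1],
                "ucr_mgdl": s.ucr[occ - 1], "serum_cr_mgdl": s.serum_cr,
            })
    return pd.DataFrame(rows, columns=STABILITY_COLUMNS)
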