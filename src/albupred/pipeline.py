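"""End-to-end report pipeline: eligibility -> classification -> binning ->
spline fit/selection -> ROC tables -> subgroups (cohort mode), or the
stability agreement/cutoff tables (stability mode).

Outputs are plain CSV reports plus a JSON summary carrying the selected
knot count, fitted coefficients, and cutoffs, and a run log with the
configuration echoed verbatim and a hash of it stamped into every file
name-value map.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    bin_summaries,
    select_knot_count,
    slope_change_tests,
)
from .cohort import (
    build_discriminators,
    delta_regression,
    distribution_crosstab,
    microalbuminuria_discrimination,
    pooled_measurements,
    subgroup_cutoffs,
    uacr_threshold_table,
)
from .core_data import (
    apply_eligibility,
    read_cohort_csv,
    write_cohort_csv,
    write_exclusion_report,
)
from .simulate import CohortTruth, StabilityTruth, generate_cohort, \
    generate_stability_study
from .stability import agreement_table, read_stability_csv, \
    stability_cutoffs, stability_to_frame

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str                               # "cohort" | "stability" | "simulate"
    input_path: str | None = None
    out_dir: str = "albupred_out"
    seed: int = 0
    knot_candidates: tuple[int, ...] = (3, 4, 5)
    uacr_thresholds: tuple[float, ...] = tuple(range(10, 151, 10)) + (300,)
    subgroup_axes: tuple[str, ...] = ("age", "sex", "gfr")
    max_bin_upcr: float = 0.50              # g/gCr, fitting domain
    n_patients: int = 303                   # simulate mode
    n_samples: int = 88                     # simulate mode

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "stability", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate" and not self.input_path:
            raise ValueError(f"mode {self.mode!r} requires an input path")
        bad = set(self.knot_candidates) - {3, 4, 5}
        if bad:
            raise ValueError(f"unsupported knot candidates {sorted(bad)}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis and write the report bundle.

    Returns the JSON-serializable summary that is also written to
    ``summary.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "mode": config.mode,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
    }
    try:
        if config.mode == "simulate":
            _run_simulate(config, out, summary)
        elif config.mode == "cohort":
            _run_cohort(config, out, summary)
        else:
            _run_stability(config, out, summary)
    except Exception:
        (out / "FAILED").write_text("run did not complete; outputs are partial\n")
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    with open(out / "run.log", "w") as fh:
        fh.write(f"albupred {__version__} python {sys.version.split()[0]}\n")
        fh.write(f"config_hash {summary['config_hash']}\n")
        fh.write(json.dumps(summary["config"], indent=2, default=str) + "\n")
    return summary


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _run_simulate(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = generate_cohort(
        CohortTruth(n_patients=config.n_patients, seed=config.seed))
    cohort.to_csv(out / "cohort.csv", index=False)
    samples = generate_stability_study(
        StabilityTruth(n_samples=config.n_samples, seed=config.seed))
    stability_to_frame(samples).to_csv(out / "stability.csv", index=False)
    summary["n_cohort_rows"] = len(cohort)
    summary["n_stability_samples"] = len(samples)


def _run_cohort(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = read_cohort_csv(config.input_path)
    kept, excluded = apply_eligibility(cohort)
    write_exclusion_report(excluded, out / "exclusions.csv")
    write_cohort_csv(kept, out / "eligible_cohort.csv")
    summary["n_input"] = len(cohort)
    summary["n_eligible"] = len(kept)

    records = pooled_measurements(kept)
    pairs = [(u, a) for u, a in zip(records["upcr"], records["uacr"])
             if 0 < u <= config.max_bin_upcr]
    bins = bin_summaries(pairs)
    pd.DataFrame([vars(b) for b in bins]).to_csv(out / "bin_medians.csv",
                                                 index=False)
    # zero bins (undetected / sub-resolution uPCR) cannot enter a log fit
    bins = [b for b in bins if b.bin_label > 0 and b.median_uacr > 0]
    x = np.log([b.bin_label * 1000.0 for b in bins])
    y = np.log([b.median_uacr for b in bins])
    raw = records.loc[records["upcr"] > 0, "upcr"].to_numpy() * 1000.0
    best_k, aic_table, model = select_knot_count(
        x, y, "linear", config.knot_candidates, raw_values=raw)
    summary["selected_knots"] = best_k
    summary["aic_table"] = aic_table
    summary["knots_mg_per_gcr"] = model.knots
    summary["segments"] = [vars(s) for s in model.segments]
    summary["adj_r2"] = model.adj_r2
    pd.DataFrame([vars(c) for c in slope_change_tests(model)]).to_csv(
        out / "slope_changes.csv", index=False)

    uacr_threshold_table(records, config.uacr_thresholds).to_csv(
        out / "uacr_threshold_roc.csv", index=False)

    ds = build_discriminators(kept)
    table, pairwise = microalbuminuria_discrimination(ds)
    table.to_csv(out / "discriminators.csv")
    pairwise.to_csv(out / "discriminator_pairwise.csv", index=False)
    summary["cutoffs"] = table["cutoff"].to_dict()

    sub = pd.concat(
        [subgroup_cutoffs(ds.frame, "uPCR2", "positive", ax)
         for ax in config.subgroup_axes],
        ignore_index=True,
    )
    sub.to_csv(out / "subgroups.csv", index=False)
    distribution_crosstab(records).to_csv(out / "crosstab.csv")
    delta_regression(ds).to_csv(out / "delta_regression.csv", index=False)


def _run_stability(config: RunConfig, out: Path, summary: dict) -> None:
    samples = read_stability_csv(config.input_path)
    summary["n_samples"] = len(samples)
    for analyte in ("up", "ualb", "ucr", "upcr", "uacr"):
        agreement_table(samples, analyte).to_csv(
            out / f"agreement_{analyte}.csv", index=False)
    cuts = stability_cutoffs(samples)
    cuts.to_csv(out / "stability_cutoffs.csv", index=False)
    ok = cuts[~cuts["degenerate"]]
    summary["upcr_cutoffs_by_occasion"] = {
        f"occ{int(r.occasion)}_{r.target}": r.upcr_cutoff
        for r in ok.itertuples()
    }
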