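"""Log-log spline calibration of median uACR on uPCR.

The calibration works on the natural-log scale of both ratios, with uPCR
expressed in mg/gCr (1000 x the g/gCr reporting unit) so that published
knots at 20/60/120/350 mg/gCr can be used directly.  The observations
fed to the regression are the occupied 0.01-g/gCr bins of the raw
(uPCR, uACR) pairs: x = ln(bin label in mg/gCr), y = ln(median uACR of
the bin).

Two spline families are supported: a continuous piecewise-linear
("mkspline"-style) fit whose per-segment intercept/slope presentation
matches how such conversion equations are published, and a restricted
cubic spline (truncated-power basis, linear beyond the boundary knots)
as a nonlinearity check.  Knot counts are chosen by Gaussian-OLS AIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BinSummary",
    "SplineModel",
    "SplineSegment",
    "SlopeChange",
    "bin_summaries",
    "fit_linear_spline",
    "fit_restricted_cubic_spline",
    "invert_median_uacr",
    "linear_spline_basis",
    "load_published_bins",
    "load_published_model",
    "predict_median_uacr",
    "restricted_cubic_basis",
    "select_knot_count",
    "slope_change_tests",
    "standard_knots",
]

#: Harrell's standard percentile locations for k = 3..5 knots.
STANDARD_KNOT_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


@dataclass(frozen=True)
class BinSummary:
    """Median uACR (with IQR) of one 0.01-g/gCr uPCR bin."""

    bin_label: float       # uPCR in g/gCr, 0.01 resolution
    n: int
    median_uacr: float     # mg/gCr
    q1: float
    q3: float


@dataclass(frozen=True)
class SplineSegment:
    """One piece of a piecewise log-linear model: [lo, hi) in mg/gCr,
    ln(uACR) = intercept + slope * ln(uPCR)."""

    lo: float
    hi: float
    intercept: float
    slope: float


@dataclass
class SlopeChange:
    """Inference on the slope difference across one interior knot."""

    pair: str              # e.g. "2R vs 3R"
    difference: float      # slope(right) - slope(left)
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class SplineModel:
    """A fitted (or published) spline on the ln(uACR)-ln(uPCR) scale."""

    kind: str                                  # "linear" | "restricted_cubic"
    knots: np.ndarray                          # mg/gCr, strictly increasing
    segments: list[SplineSegment] = field(default_factory=list)
    basis_coefficients: np.ndarray | None = None
    covariance: np.ndarray | None = None
    aic: float = np.nan
    adj_r2: float = np.nan
    rss: float = np.nan
    n: int = 0
    p: int = 0                                 # regression coefficients
    df_resid: int = 0
    domain: tuple[float, float] = (0.0, np.inf)  # mg/gCr, (lo, hi]
    population: str = ""

    def predict_ln(self, ln_upcr):
        """ln(median uACR) at ln(uPCR in mg/gCr); vectorized."""
        x = np.asarray(ln_upcr, dtype=float)
        if self.kind == "linear":
            out = np.empty_like(x)
            upcr = np.exp(x)
            filled = np.zeros(x.shape, dtype=bool)
            for seg in self.segments:
                mask = (upcr >= seg.lo) & (upcr < seg.hi) & ~filled
                out[mask] = seg.intercept + seg.slope * x[mask]
                filled |= mask
            # right-closed at the final boundary
            last = self.segments[-1]
            mask = np.isclose(upcr, last.hi) & ~filled
            out[mask] = last.intercept + last.slope * x[mask]
            filled |= mask
            if not filled.all():
                raise ValueError("uPCR outside the model's segment ranges")
            return out
        basis = restricted_cubic_basis(x, np.log(self.knots))
        X = np.column_stack([np.ones_like(x), basis])
        return X @ self.basis_coefficients


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(q1, median, q3) by linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def bin_summaries(pairs, bin_width: float = 0.01) -> list[BinSummary]:
    """Summarize (uPCR g/gCr, uACR mg/gCr) pairs per uPCR bin.

    Bin membership is nearest-multiple rounding of uPCR to ``bin_width``;
    the bin label is that rounded value, matching tables that label bins
    by single uPCR values rather than ranges.
    """
    pairs = [(float(u), float(a)) for u, a in pairs]
    if not pairs:
        raise ValueError("no (uPCR, uACR) pairs supplied")
    if any(u < 0 for u, _ in pairs):
        raise ValueError("uPCR must be non-negative")
    bins: dict[float, list[float]] = {}
    for u, a in pairs:
        label = round(round(u / bin_width) * bin_width, 10)
        bins.setdefault(label, []).append(a)
    out = []
    for label in sorted(bins):
        vals = np.asarray(bins[label])
        q1, med, q3 = _quartiles(vals)
        out.append(BinSummary(label, len(vals), med, q1, q3))
    return out


def standard_knots(values, k: int) -> np.ndarray:
    """Knots at the standard percentile locations of the raw measurements.

    ``values`` are uPCR in mg/gCr (the raw per-measurement distribution,
    not bin labels). Percentiles use linear interpolation between order
    statistics.
    """
    if k not in STANDARD_KNOT_PERCENTILES:
        raise ValueError(f"supported knot counts are 3, 4, 5; got {k}")
    knots = np.percentile(
        np.asarray(values, dtype=float),
        STANDARD_KNOT_PERCENTILES[k],
        method="linear",
    )
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "knot locations are not strictly increasing; "
            "try fewer knots or more distinct values"
        )
    return knots


def linear_spline_basis(x, knots) -> np.ndarray:
    """Continuous piecewise-linear basis (without intercept column).

    Column 1 is min(x, k1); column j (2..m) is clamp(x - k_{j-1}, 0,
    k_j - k_{j-1}); the final column is max(x - k_m, 0).  The coefficient
    of each column is the slope of the corresponding segment.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    cols = [np.minimum(x, knots[0])]
    for j in range(1, len(knots)):
        cols.append(np.clip(x - knots[j - 1], 0.0, knots[j] - knots[j - 1]))
    cols.append(np.maximum(x - knots[-1], 0.0))
    return np.column_stack(cols)


def restricted_cubic_basis(x, knots) -> np.ndarray:
    """Restricted cubic (natural) spline truncated-power basis.

    For knots t_1 < ... < t_k returns k-1 columns: x itself and, for
    j = 1..k-2, the cubic term constrained to be linear beyond the
    boundary knots:

        (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("restricted cubic spline requires >= 3 knots")

    def plus3(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        cols.append(
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / denom
            + plus3(x - t[-1]) * (t[-2] - t[j]) / denom
        )
    return np.column_stack(cols)


def _gaussian_aic(n: int, rss: float, n_coef: int) -> float:
    """AIC = n ln(RSS/n) + 2(p+1); p regression coefficients plus sigma^2."""
    return float(n * np.log(rss / n) + 2 * (n_coef + 1))


def _fit_ols(X: np.ndarray, y: np.ndarray, weights=None):
    if weights is None:
        return sm.OLS(y, X).fit()
    return sm.WLS(y, X, weights=np.asarray(weights, dtype=float)).fit()


def fit_linear_spline(x, y, knots, weights=None) -> SplineModel:
    """Continuous piecewise-linear least squares of y on x with given knots.

    x is ln(uPCR in mg/gCr), y is ln(median uACR in mg/gCr); knots are in
    mg/gCr.  Per-segment (intercept, slope) pairs are cumulated from the
    basis coefficients so adjacent segments agree exactly at each knot.

    ``weights`` (optional) are WLS weights, typically the per-bin counts
    when the observations are bin medians: the sampling variance of a bin
    median scales as 1/n, so unweighted fitting over-trusts sparse bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    knots = np.asarray(knots, dtype=float)
    ln_knots = np.log(knots)
    basis = linear_spline_basis(x, ln_knots)
    X = np.column_stack([np.ones_like(x), basis])
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} points for {len(knots)} knots")
    edges = np.concatenate([[-np.inf], ln_knots, [np.inf]])
    empty = [
        i + 1
        for i in range(len(edges) - 1)
        if not np.any((x >= edges[i]) & (x < edges[i + 1]))
    ]
    if empty:
        raise ValueError(f"no observations in segment(s) {empty}; "
                         "reduce the knot count or extend the data")
    res = _fit_ols(X, y, weights)
    b = res.params
    # segment slopes are the basis coefficients; intercepts cumulate for
    # continuity: a_{j+1} = a_j + (b_j - b_{j+1}) * ln(k_j)
    slopes = b[1:]
    intercepts = [b[0]]
    for j in range(len(knots)):
        intercepts.append(intercepts[-1] + (slopes[j] - slopes[j + 1]) * ln_knots[j])
    bounds = np.concatenate([[0.0], knots, [np.inf]])
    segments = [
        SplineSegment(bounds[j], bounds[j + 1], float(intercepts[j]), float(slopes[j]))
        for j in range(len(slopes))
    ]
    rss = float(res.ssr)
    return SplineModel(
        kind="linear",
        knots=knots,
        segments=segments,
        basis_coefficients=np.asarray(b),
        covariance=np.asarray(res.cov_params()),
        aic=_gaussian_aic(n, rss, p),
        adj_r2=float(res.rsquared_adj),
        rss=rss,
        n=n,
        p=p,
        df_resid=int(res.df_resid),
        domain=(float(np.exp(x.min())), float(np.exp(x.max()))),
    )


def fit_restricted_cubic_spline(x, y, knots) -> SplineModel:
    """Restricted cubic spline least squares on the same ln-ln scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("restricted cubic spline requires >= 3 knots")
    basis = restricted_cubic_basis(x, np.log(knots))
    X = np.column_stack([np.ones(len(x)), basis])
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} points for {len(knots)} knots")
    res = _fit_ols(X, y)
    rss = float(res.ssr)
    return SplineModel(
        kind="restricted_cubic",
        knots=knots,
        basis_coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        aic=_gaussian_aic(n, rss, p),
        adj_r2=float(res.rsquared_adj),
        rss=rss,
        n=n,
        p=p,
        df_resid=int(res.df_resid),
        domain=(float(np.exp(x.min())), float(np.exp(x.max()))),
    )


_FITTERS = {
    "linear": fit_linear_spline,
    "restricted_cubic": fit_restricted_cubic_spline,
}


def select_knot_count(x, y, kind: str = "linear", candidates=(3, 4, 5),
                      raw_values=None):
    """Choose the knot count minimizing AIC; ties go to the smaller k.

    ``raw_values`` (uPCR mg/gCr) define the percentile knots; by default
    exp(x) of the regression points is used.
    """
    if raw_values is None:
        raw_values = np.exp(np.asarray(x, dtype=float))
    fitter = _FITTERS[kind]
    table = {}
    for k in sorted(candidates):
        knots = standard_knots(raw_values, k)
        table[k] = fitter(x, y, knots)
    best_k = min(table, key=lambda k: (round(table[k].aic, 12), k))
    return best_k, {k: m.aic for k, m in table.items()}, table[best_k]


def slope_change_tests(model: SplineModel) -> list[SlopeChange]:
    """t tests on the slope change at each interior knot of a linear spline.

    The difference is slope(right segment) - slope(left segment); its SE
    comes from the fitted coefficient covariance via the contrast vector,
    with a Student-t reference on the residual degrees of freedom.
    """
    if model.kind != "linear":
        raise ValueError("slope changes are defined for linear splines")
    if model.covariance is None:
        raise ValueError("model has no coefficient covariance (published "
                         "coefficient sets carry point estimates only)")
    V = model.covariance
    b = model.basis_coefficients
    out = []
    for j in range(1, len(b) - 1):  # basis coefs 1..m+1 are segment slopes
        c = np.zeros(len(b))
        c[j], c[j + 1] = -1.0, 1.0
        diff = float(c @ b)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        df = model.df_resid
        if se <= 1e-10:
            # exact-fit degeneracy: no evidence either way below tolerance
            t = 0.0 if abs(diff) <= 1e-10 else np.sign(diff) * np.inf
            p = 1.0 if t == 0.0 else 0.0
            half = 0.0
        else:
            t = diff / se
            p = 2 * stats.t.sf(abs(t), df)
            half = stats.t.ppf(0.975, df) * se
        out.append(SlopeChange(
            pair=f"{j}R vs {j + 1}R",
            difference=diff, se=se, t=t, p=float(p),
            ci_low=diff - half, ci_high=diff + half,
        ))
    return out


def predict_median_uacr(model: SplineModel, upcr_mg: float):
    """Median uACR (mg/gCr) predicted at uPCR (mg/gCr); no extrapolation.

    Raises ValueError outside the model's domain.
    """
    x = np.asarray(upcr_mg, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo, hi = model.domain
    if np.any(x <= 0) or np.any(x < lo) or np.any(x > hi):
        raise ValueError(
            f"uPCR must lie within the model domain ({lo:g}, {hi:g}] mg/gCr"
        )
    y = np.exp(model.predict_ln(np.log(x)))
    return float(y[0]) if scalar else y


def invert_median_uacr(model: SplineModel, target_uacr: float) -> float:
    """uPCR (mg/gCr) at which the model predicts the target median uACR.

    Requires a piecewise-monotone-increasing linear model; solved in
    closed form segment by segment.
    """
    if model.kind != "linear":
        raise ValueError("closed-form inversion requires a linear spline")
    bad = [i + 1 for i, s in enumerate(model.segments) if s.slope <= 0]
    if bad:
        raise ValueError(f"model is not monotone increasing on segment(s) {bad}")
    ln_t = np.log(target_uacr)
    lo_dom, hi_dom = model.domain
    for seg in model.segments:
        lo = max(seg.lo, lo_dom)
        hi = min(seg.hi, hi_dom)
        if lo >= hi:
            continue
        y_lo = seg.intercept + seg.slope * np.log(lo)
        y_hi = seg.intercept + seg.slope * np.log(hi)
        if y_lo <= ln_t <= y_hi:
            return float(np.exp((ln_t - seg.intercept) / seg.slope))
    raise ValueError(
        f"target uACR {target_uacr} mg/gCr is outside the model's predicted "
        f"range over its domain ({lo_dom:g}, {hi_dom:g}] mg/gCr"
    )


# ---------------------------------------------------------------------------
# Published coefficient registry

def _load_data(name: str) -> dict:
    with resources.files("albupred.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_published_model(population: str = "all",
                         registry_path=None) -> SplineModel:
    """Load a published piecewise log-linear coefficient set.

    ``population`` is one of ``all``, ``non_diabetic``, ``diabetic`` for
    the bundled registry; ``registry_path`` may point at a JSON file with
    the same schema to plug in other published coefficient sets (e.g.
    externally published conversion equations).
    """
    if registry_path is not None:
        with open(registry_path) as fh:
            reg = json.load(fh)
    else:
        reg = _load_data("published_spline_coefficients.json")
    try:
        entry = reg["populations"][population]
    except KeyError:
        raise KeyError(
            f"unknown population {population!r}; available: "
            f"{sorted(reg['populations'])}"
        ) from None
    segments = [
        SplineSegment(s["lo"], s["hi"], s["intercept"], s["slope"])
        for s in entry["segments"]
    ]
    lo, hi = reg["domain_mg_per_gcr"]
    return SplineModel(
        kind="linear",
        knots=np.asarray(reg["knots_mg_per_gcr"], dtype=float),
        segments=segments,
        domain=(float(lo), float(hi)),
        population=population,
    )


def load_published_bins(population: str = "all") -> list[BinSummary]:
    """Published per-bin median uACR summaries (uPCR 0.01-0.16 g/gCr)."""
    reg = _load_data("published_bin_medians.json")
    return [
        BinSummary(r["upcr"], r["n"], r["median"], r["q1"], r["q3"])
        for r in reg["populations"][population]
    ]
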