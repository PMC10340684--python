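"""Cohort statistics: correlations, laterality tests, and power analysis.

Implements the statistical layer of the pipeline:

* Pearson correlations (with univariate least-squares regression lines)
  between side-averaged joint uptake and clinical covariates, with
  pairwise deletion of missing values so the effective n varies per cell;
* paired t-tests for left/right laterality differences per joint and
  tracer, optionally restricted to right-handed subjects;
* the minimal detectable correlation for a given sample size, power, and
  alpha via the Fisher-z sample-size approximation
  ``n = ((z_{1-α/2} + z_{power}) / atanh(r))² + 3``.

Two-sided tests throughout.  No multiple-testing correction is applied by
default; Benjamini–Hochberg q-values can be annotated on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairedTestResult",
    "CohortReport",
    "CLINICAL_VARIABLES",
    "UPTAKE_JOINTS",
    "TRACERS",
    "pearson_corr",
    "corr_pvalue",
    "paired_t",
    "min_detectable_r",
    "cohort_analysis",
    "validate_cohort_table",
    "uptake_column",
]

#: Clinical covariate columns of a cohort table, in report order.
CLINICAL_VARIABLES = (
    "age",
    "weight",
    "height",
    "bmi",
    "leptin",
    "sclerostin",
    "total_fat",
    "crp",
    "esr",
    "il1",
    "il6",
    "das28_crp",
    "vas_ptglobal",
)

UPTAKE_JOINTS = ("knee", "hip", "si")
TRACERS = ("fdg", "naf")


def uptake_column(tracer: str, joint: str, side: str | None = None) -> str:
    """Canonical cohort-table column name for an uptake value.

    Side-averaged: ``fdg_knee``; per side: ``fdg_knee_left``.
    """
    base = f"{tracer.lower()}_{joint.lower()}"
    return base if side is None else f"{base}_{side}"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one variable pair with its regression line."""

    var_x: str
    var_y: str
    r: float
    n_used: int
    p: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be ≤ 1, got {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test of right − left uptake for one joint and tracer."""

    joint: str
    tracer: str
    n_pairs: int
    mean_difference: float
    t: float
    p: float


@dataclass
class CohortReport:
    """Correlation matrices per joint plus laterality tests.

    ``correlations[joint]`` is a DataFrame indexed by clinical variable with
    columns ``(tracer, {r, p, n})`` for each tracer; unavailable cells
    (insufficient overlapping data) are NaN.
    """

    correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    laterality: list[PairedTestResult] = field(default_factory=list)
    details: list[CorrelationResult] = field(default_factory=list)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_corr(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Sample Pearson correlation of ``y`` against ``x`` after pairwise deletion.

    The two-sided p-value comes from the t-transform
    ``t = r·sqrt(n−2)/sqrt(1−r²)`` with n−2 degrees of freedom; the slope
    and intercept are the least-squares fit of y on x.  Requires at least 3
    complete pairs and nonzero variance in both variables.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("degenerate variable: zero variance after pairwise deletion")
    fit = sps.linregress(xv, yv)
    r = float(np.clip(fit.rvalue, -1.0, 1.0))
    return CorrelationResult(
        var_x=var_x,
        var_y=var_y,
        r=r,
        n_used=n,
        p=corr_pvalue(r, n),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t-transform.

    ``t = r·sqrt(n−2)/sqrt(1−r²)`` with n−2 df.  For |r| ≥ 1 the limiting
    value 0 is returned.  Strictly decreasing in |r| for fixed n ≥ 3.
    """
    if n < 3:
        raise ValueError(f"need n ≥ 3, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(left, right, joint: str = "", tracer: str = "") -> PairedTestResult:
    """Classical paired t-test on right − left differences (two-sided).

    Pairs with a missing value on either side are dropped.  When every
    difference is exactly zero the test degenerates to t = 0, p = 1.
    """
    lv, rv = _pairwise_complete(left, right)
    n = len(lv)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    diff = rv - lv
    if np.all(diff == 0):
        return PairedTestResult(joint, tracer, n, 0.0, 0.0, 1.0)
    if np.ptp(diff) == 0:
        # constant nonzero difference: infinite t, p -> 0
        return PairedTestResult(
            joint, tracer, n, float(diff.mean()), math.copysign(math.inf, diff.mean()), 0.0
        )
    res = sps.ttest_rel(rv, lv)
    return PairedTestResult(
        joint=joint,
        tracer=tracer,
        n_pairs=n,
        mean_difference=float(diff.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
    )


def min_detectable_r(n: int, power: float = 0.8, alpha: float = 0.05) -> float:
    """Smallest Pearson r detectable at sample size ``n`` with given power.

    Solves the Fisher-z sample-size approximation
    ``n = ((z_{1−α/2} + z_{power}) / atanh(r))² + 3`` for r by bisection to
    1e-6.  Decreasing in n; requires n ≥ 4.
    """
    if n < 4:
        raise ValueError(f"need n ≥ 4 for a finite detectable correlation, got {n}")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    z_sum = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)

    def required_n(r: float) -> float:
        return (z_sum / math.atanh(r)) ** 2 + 3

    lo, hi = 1e-12, 1.0 - 1e-15
    if required_n(hi) > n:
        raise ValueError(f"no r < 1 is detectable at n = {n} with the given power/alpha")
    # required_n is strictly decreasing in r; bisect for required_n(r) = n
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if required_n(mid) > n:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def validate_cohort_table(table: pd.DataFrame, bmi_tol: float = 0.1) -> None:
    """Check cohort-table invariants: unique subject ids and BMI consistency.

    BMI must agree with weight/(height in m)² to ``bmi_tol`` on rows where
    all three are present.
    """
    if "subject" in table.columns:
        ids = table["subject"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dup}")
    cols = {"weight", "height", "bmi"}
    if cols.issubset(table.columns):
        sub = table[list(cols)].dropna()
        implied = sub["weight"] / (sub["height"] / 100.0) ** 2
        bad = (implied - sub["bmi"]).abs() > bmi_tol
        if bad.any():
            raise ValueError(
                f"BMI inconsistent with weight/height on rows {list(sub.index[bad])}"
            )


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def cohort_analysis(
    table: pd.DataFrame,
    joints=UPTAKE_JOINTS,
    tracers=TRACERS,
    clinical=CLINICAL_VARIABLES,
    right_handed_only: bool = False,
    bh_qvalues: bool = False,
) -> CohortReport:
    """Build per-joint correlation matrices and laterality tests.

    For every (joint, tracer) side-averaged uptake column present in the
    table, each clinical variable is correlated with pairwise deletion;
    cells with fewer than 3 complete pairs or a degenerate variable are
    reported as NaN.  Per-side columns (``*_left``/``*_right``), when
    present, feed paired laterality t-tests.  ``right_handed_only``
    restricts the laterality tests to right-handed subjects (requires a
    ``handedness`` column).  ``bh_qvalues`` adds a ``q`` level with
    Benjamini–Hochberg adjusted p-values per joint.
    """
    validate_cohort_table(table)
    clinical = [c for c in clinical if c in table.columns]
    if not clinical:
        raise ValueError("cohort table has no recognized clinical columns")
    report = CohortReport()
    for joint in joints:
        blocks: dict[tuple[str, str], pd.Series] = {}
        any_uptake = False
        for tracer in tracers:
            col = uptake_column(tracer, joint)
            rs, ps, ns = {}, {}, {}
            for var in clinical:
                rs[var], ps[var], ns[var] = np.nan, np.nan, np.nan
                if col in table.columns:
                    try:
                        res = pearson_corr(table[var], table[col], var, col)
                    except ValueError:
                        continue
                    rs[var], ps[var], ns[var] = res.r, res.p, res.n_used
                    report.details.append(res)
            if col in table.columns:
                any_uptake = True
            blocks[(tracer, "r")] = pd.Series(rs)
            blocks[(tracer, "p")] = pd.Series(ps)
            blocks[(tracer, "n")] = pd.Series(ns)
            if bh_qvalues:
                blocks[(tracer, "q")] = pd.Series(
                    _bh_qvalues(pd.Series(ps).to_numpy(dtype=float)),
                    index=list(ps),
                )
        if any_uptake:
            df = pd.DataFrame(blocks).reindex(clinical)
            df.columns = pd.MultiIndex.from_tuples(df.columns, names=["tracer", "stat"])
            report.correlations[joint] = df
        lat_table = table
        if right_handed_only:
            if "handedness" not in table.columns:
                raise ValueError("right_handed_only requires a 'handedness' column")
            lat_table = table[table["handedness"] == "right"]
        for tracer in tracers:
            lcol = uptake_column(tracer, joint, "left")
            rcol = uptake_column(tracer, joint, "right")
            if lcol in lat_table.columns and rcol in lat_table.columns:
                try:
                    report.laterality.append(
                        paired_t(lat_table[lcol], lat_table[rcol], joint, tracer)
                    )
                except ValueError:
                    pass
    return report
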