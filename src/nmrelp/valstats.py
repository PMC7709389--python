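"""Clinical validation statistics battery.

Summary statistics in the style used to validate clinical chemistry assays:
within-run / within-lab precision, limit of blank / detection / quantitation,
linearity against mixed pools, non-weighted Deming regression for method
comparison, percent bias against reference targets, interference and
stability screens, and collection-tube comparison by linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PrecisionResult",
    "SensitivityResult",
    "DemingFit",
    "BiasRecord",
    "LinearityResult",
    "InterferenceResult",
    "StabilityResult",
    "TubeComparisonResult",
    "precision_summary",
    "sensitivity_limits",
    "deming_fit",
    "linearity_eval",
    "percent_bias",
    "mean_absolute_bias",
    "interference_eval",
    "stability_eval",
    "tube_comparison",
]

#: One-sided 95th-percentile normal quantile used in LOB/LOD estimation.
_Z95 = 1.645


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# Precision
# ---------------------------------------------------------------------------

@dataclass
class PrecisionResult:
    """Per-pool mean / SD / CV% for one precision design."""

    design: str  # within_run | within_lab
    pools: dict[str, dict[str, float]]  # pool -> {mean, sd, cv_pct, n}


def precision_summary(replicates_by_pool: dict, design: str = "within_run") -> PrecisionResult:
    """Mean, sample SD (n-1 denominator) and CV% per pool.

    For the within-lab design the replicate set per pool is simply all
    results across days/runs (e.g. the 80 results of a 20-day duplicate
    design); the total SD over those results is reported.
    """
    if design not in ("within_run", "within_lab"):
        raise ValueError(f"unknown design {design!r}")
    if not replicates_by_pool:
        raise ValueError("no pools provided")
    pools = {}
    for pool, values in replicates_by_pool.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"pool {pool!r}: need >= 2 replicates")
        mean = float(v.mean())
        sd = _sample_sd(v)
        if mean == 0:
            raise ValueError(f"pool {pool!r}: zero mean, CV undefined")
        pools[pool] = {
            "mean": mean,
            "sd": sd,
            "cv_pct": 100.0 * sd / mean,
            "n": int(v.size),
        }
    return PrecisionResult(design=design, pools=pools)


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """LOB / LOD / LOQ (mg/dL) with the inputs that produced them."""

    lob: float
    lod: float
    loq: float | None          # None when no dilution level meets the CV limit
    loq_reached: bool
    blank_mean: float
    blank_sd: float
    low_pooled_sd: float
    cv_limit: float
    levels: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lob <= self.lod + 1e-12:
            raise ValueError("LOB must not exceed LOD")
        if self.loq_reached and self.loq is not None and self.loq < self.lod - 1e-12:
            raise ValueError("LOQ must not fall below LOD")


def sensitivity_limits(
    blanks, low_pools, dilution_series=(), cv_limit: float = 20.0
) -> SensitivityResult:
    """Assay sensitivity bounds.

    LOB = blank mean + 1.645 * blank SD; LOD = LOB + 1.645 * pooled SD of the
    low-level pools (dof-weighted); LOQ = mean of the lowest dilution level
    whose replicate CV <= ``cv_limit`` percent and whose mean >= LOD (the
    monotone ordering LOB <= LOD <= LOQ is enforced by construction).
    """
    b = np.asarray(blanks, dtype=float)
    if b.size == 0:
        raise ValueError("no blank replicates")
    blank_sd = _sample_sd(b) if b.size > 1 else 0.0
    lob = float(b.mean()) + _Z95 * blank_sd
    pools = [np.asarray(p, dtype=float) for p in low_pools]
    if not pools:
        raise ValueError("need at least one low-level pool")
    dofs = np.array([p.size - 1 for p in pools])
    if dofs.sum() > 0:
        pooled_var = sum((p.size - 1) * np.var(p, ddof=1) for p in pools if p.size > 1)
        low_sd = float(np.sqrt(pooled_var / dofs.sum()))
    else:
        low_sd = 0.0
    lod = lob + _Z95 * low_sd

    levels = []
    for level, reps in dilution_series:
        r = np.asarray(reps, dtype=float)
        if r.size < 2:
            raise ValueError(f"dilution level {level!r}: need >= 2 replicates")
        mean = float(r.mean())
        cv = 100.0 * _sample_sd(r) / mean if mean != 0 else np.inf
        levels.append({"level": level, "mean": mean, "cv_pct": cv})
    qualifying = [
        lv["mean"] for lv in levels if lv["cv_pct"] <= cv_limit and lv["mean"] >= lod
    ]
    loq = min(qualifying) if qualifying else None
    return SensitivityResult(
        lob=lob,
        lod=lod,
        loq=loq,
        loq_reached=loq is not None,
        blank_mean=float(b.mean()),
        blank_sd=blank_sd,
        low_pooled_sd=low_sd,
        cv_limit=cv_limit,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# Method comparison (Deming)
# ---------------------------------------------------------------------------

@dataclass
class DemingFit:
    """Non-weighted Deming regression with unit error-variance ratio."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Deming fit needs n >= 3")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite Deming fit")


def deming_fit(x, y) -> DemingFit:
    """Errors-in-both-variables line fit, lambda = 1 closed form.

    slope = [S_yy - S_xx + sqrt((S_yy - S_xx)^2 + 4 S_xy^2)] / (2 S_xy),
    intercept = ybar - slope * xbar, with S the centered sums of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matched 1-D arrays of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0:
        raise ValueError("degenerate comparator: all x equal")
    if sxy == 0.0:
        raise ValueError("no covariance between methods; Deming slope undefined")
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    r = float(sxy / np.sqrt(sxx * syy)) if syy > 0 else float("nan")
    return DemingFit(slope=float(slope), intercept=intercept, pearson_r=r, n=x.size)


# ---------------------------------------------------------------------------
# Linearity
# ---------------------------------------------------------------------------

@dataclass
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    mixtures: list[dict[str, float]]   # fraction, expected, measured, deviation_pct
    max_abs_deviation_pct: float
    deviation_limit_pct: float
    flagged: bool


def linearity_eval(
    mixtures, low_value: float, high_value: float, deviation_limit_pct: float = 10.0
) -> LinearityResult:
    """Expected-vs-measured linearity over serially mixed pools.

    expected = (1 - f) * low + f * high for mixing fraction f; measured is
    the replicate mean; a first-order fit of measured on expected and the
    per-mixture percent deviation are reported.
    """
    rows = []
    for fraction, reps in mixtures:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"mixing fraction {fraction} outside [0, 1]")
        r = np.asarray(reps, dtype=float)
        if r.size == 0:
            raise ValueError("mixture with no replicates")
        expected = (1.0 - fraction) * low_value + fraction * high_value
        measured = float(r.mean())
        if expected == 0:
            raise ValueError("expected value of 0; deviation undefined")
        rows.append(
            {
                "fraction": float(fraction),
                "expected": expected,
                "measured": measured,
                "deviation_pct": 100.0 * (measured - expected) / expected,
            }
        )
    if not rows:
        raise ValueError("no mixtures provided")
    exp = np.array([r["expected"] for r in rows])
    meas = np.array([r["measured"] for r in rows])
    if np.ptp(exp) > 0:
        slope, intercept = np.polyfit(exp, meas, 1)
        ss_res = float(np.sum((meas - (slope * exp + intercept)) ** 2))
        ss_tot = float(np.sum((meas - meas.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        # a single mixture level: deviations are still meaningful, a line is not
        slope = intercept = r2 = float("nan")
    max_dev = max(abs(r["deviation_pct"]) for r in rows)
    return LinearityResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        mixtures=rows,
        max_abs_deviation_pct=max_dev,
        deviation_limit_pct=deviation_limit_pct,
        flagged=max_dev > deviation_limit_pct,
    )


# ---------------------------------------------------------------------------
# Bias
# ---------------------------------------------------------------------------

@dataclass
class BiasRecord:
    """One measured-vs-target comparison (e.g. a CDC reference pool)."""

    measured: float
    target: float
    source: str = ""
    bias_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.bias_pct = percent_bias(self.measured, self.target)


def percent_bias(measured: float, target: float) -> float:
    """100 * (measured - target) / target."""
    if target == 0:
        raise ValueError("target must be nonzero")
    return 100.0 * (measured - target) / target


def mean_absolute_bias(records) -> float:
    """Mean of |bias%| over a set of BiasRecords."""
    records = list(records)
    if not records:
        raise ValueError("no bias records")
    return float(np.mean([abs(r.bias_pct) for r in records]))


# ---------------------------------------------------------------------------
# Interference and stability
# ---------------------------------------------------------------------------

@dataclass
class InterferenceResult:
    percent_change: float
    flagged: bool          # strict: |change| > 10%
    control_mean: float
    test_mean: float


def interference_eval(
    control, test, limit_pct: float = 10.0
) -> InterferenceResult:
    """Percent change of spiked vs control means; flagged when strictly > 10%."""
    c = np.asarray(control, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("control and test must be non-empty")
    if c.mean() == 0:
        raise ValueError("zero control mean")
    change = 100.0 * (t.mean() - c.mean()) / c.mean()
    return InterferenceResult(
        percent_change=float(change),
        flagged=abs(change) > limit_pct,
        control_mean=float(c.mean()),
        test_mean=float(t.mean()),
    )


@dataclass
class StabilityResult:
    baseline: float
    timepoints: list[dict]   # label, value, diff_pct, acceptable
    all_acceptable: bool


def stability_eval(baseline: float, timepoints, limit_pct: float = 10.0) -> StabilityResult:
    """Percent difference of each timepoint mean from baseline.

    Acceptable iff |diff| <= 10% (inclusive: "within +/-10%").
    """
    if baseline == 0:
        raise ValueError("zero baseline")
    rows = []
    for label, value in timepoints:
        diff = 100.0 * (value - baseline) / baseline
        rows.append(
            {
                "label": label,
                "value": float(value),
                "diff_pct": float(diff),
                "acceptable": abs(diff) <= limit_pct,
            }
        )
    return StabilityResult(
        baseline=float(baseline),
        timepoints=rows,
        all_acceptable=all(r["acceptable"] for r in rows),
    )


# ---------------------------------------------------------------------------
# Tube comparison
# ---------------------------------------------------------------------------

@dataclass
class TubeComparisonResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    mean_proportional_diff_pct: float
    flagged: bool
    n: int


def tube_comparison(
    reference_tube, test_tube, slope_limit: float = 0.10, bias_limit_pct: float = 10.0
) -> TubeComparisonResult:
    """OLS of test-tube values on reference-tube values, with 95% CIs.

    Flagged when the slope deviates from 1 by more than ``slope_limit`` or
    the mean proportional difference exceeds ``bias_limit_pct`` percent.
    """
    ref = np.asarray(reference_tube, dtype=float)
    tst = np.asarray(test_tube, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1 or ref.size < 3:
        raise ValueError("need matched 1-D arrays with >= 3 pairs")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate reference values")
    if np.any(ref == 0):
        raise ValueError("zero reference value; proportional difference undefined")
    fit = sm.OLS(tst, sm.add_constant(ref)).fit()
    ci = fit.conf_int(alpha=0.05)
    prop = float(np.mean(100.0 * (tst - ref) / ref))
    slope = float(fit.params[1])
    return TubeComparisonResult(
        slope=slope,
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        mean_proportional_diff_pct=prop,
        flagged=abs(slope - 1.0) > slope_limit or abs(prop) > bias_limit_pct,
        n=ref.size,
    )
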