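"""Agreement and accuracy statistics for eREE vs mREE.

Conventions (all computed at full precision; rounding happens only in
report rendering):

* absolute bias  = eREE - mREE                       [kcal/day]
* percent bias   = 100 * (eREE - mREE) / mREE        [%]
* MAPE           = mean |percent bias|               [%]
* CCF            = fraction with |percent bias| <= threshold (default 10%,
                   boundary inclusive), with exact Clopper-Pearson 95% CIs
* Bland-Altman   = (average, difference) point sets plus an OLS test of
                   proportional bias (slope of percent difference on the
                   average); limits of agreement are deliberately not
                   computed, since they are meaningless under proportional
                   bias
* summaries      = median and IQR (25th/75th), linear interpolation between
                   closest ranks
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ALL_CHILDREN,
    STRATA,
    DomainError,
    StageError,
    Stratum,
    StudyConfig,
    Subject,
    ValidationError,
)


@dataclass(frozen=True)
class PairedSeries:
    """Index-aligned measured and estimated REE for one group of subjects."""

    mree: np.ndarray
    eree: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mree, float)
        e = np.asarray(self.eree, float)
        object.__setattr__(self, "mree", m)
        object.__setattr__(self, "eree", e)
        if m.shape != e.shape or m.ndim != 1:
            raise ValidationError("mree and eree must be 1-d and equally long")
        if len(m) < 1:
            raise ValidationError("empty paired series")
        if np.any(m <= 0):
            raise DomainError("mree must be strictly positive (it is a denominator)")

    def __len__(self) -> int:
        return len(self.mree)


def absolute_bias(pair: PairedSeries) -> np.ndarray:
    """Elementwise eREE - mREE, kcal/day."""
    return pair.eree - pair.mree


def percent_bias(pair: PairedSeries) -> np.ndarray:
    """Elementwise 100*(eREE - mREE)/mREE."""
    return 100.0 * (pair.eree - pair.mree) / pair.mree


def mape(pair: PairedSeries) -> float:
    """Mean absolute percent error: mean of |percent bias|."""
    return float(np.mean(np.abs(percent_bias(pair))))


def ccf(pair: PairedSeries, threshold_pct: float = 10.0) -> tuple[int, float]:
    """Correct classification count and fraction.

    A subject is correctly classified when |percent bias| <= threshold_pct
    (boundary inclusive).
    """
    if threshold_pct <= 0:
        raise ValidationError("threshold_pct must be positive")
    within = np.abs(percent_bias(pair)) <= threshold_pct
    count = int(within.sum())
    return count, count / len(pair)


def clopper_pearson(count: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Inverts the binomial tails via Beta quantiles:
    low  = BetaInv(alpha/2; count, n-count+1),  0 when count = 0
    high = BetaInv(1-alpha/2; count+1, n-count), 1 when count = n
    """
    if n < 1 or not (0 <= count <= n):
        raise ValidationError(f"invalid count/n: {count}/{n}")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if count == 0 else float(stats.beta.ppf(alpha / 2.0, count, n - count + 1))
    high = 1.0 if count == n else float(stats.beta.ppf(1.0 - alpha / 2.0, count + 1, n - count))
    return low, high


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th) percentiles, linear rank interpolation."""
    a = np.asarray(values, float)
    if a.size == 0:
        raise ValidationError("empty input")
    q50, q25, q75 = np.percentile(a, [50, 25, 75], method="linear")
    return float(q50), float(q25), float(q75)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding used by every rendered report cell."""
    q = Decimal(1).scaleb(-decimals)
    # + 0.0 normalises negative zero so report cells never print "-0"
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)) + 0.0


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement point sets and the proportional-bias regression.

    averages[i] = (eREE_i + mREE_i)/2; the slope is from an OLS fit of the
    percent differences on the averages; proportional_bias_flag is True at
    two-sided p < 0.05.
    """

    averages: np.ndarray = field(repr=False)
    abs_differences: np.ndarray = field(repr=False)
    pct_differences: np.ndarray = field(repr=False)
    slope: float
    slope_se: float
    slope_p: float
    proportional_bias_flag: bool


def bland_altman(pair: PairedSeries, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of eREE vs mREE without limits of agreement."""
    if len(pair) < 3:
        raise ValidationError("Bland-Altman needs at least 3 pairs")
    avg = (pair.eree + pair.mree) / 2.0
    diff = absolute_bias(pair)
    pct = percent_bias(pair)
    slope, _, se, p = _ols_slope(avg, pct)
    return BlandAltmanResult(
        averages=avg,
        abs_differences=diff,
        pct_differences=pct,
        slope=slope,
        slope_se=se,
        slope_p=p,
        proportional_bias_flag=bool(p < alpha),
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    # simple-regression slope with classic OLS standard error and t-test
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return 0.0, float(y.mean()), float("inf"), 1.0
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    dof = n - 2
    if dof <= 0:
        return slope, intercept, float("nan"), float("nan")
    s2 = float(resid @ resid) / dof
    se = (s2 / sxx) ** 0.5
    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = 2.0 * stats.t.sf(abs(slope / se), dof)
    return slope, intercept, se, float(p)


# --------------------------------------------------------------------------
# paired median difference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianDifferenceResult:
    median_diff: float
    p_value: float
    method: str       # "quantreg_robust" or "bootstrap"
    degenerate: bool = False


def paired_median_difference(
    pair: PairedSeries, n_boot: int = 2000, seed: int = 0, method: str = "bootstrap"
) -> MedianDifferenceResult:
    """Median of the paired differences with a two-sided p-value.

    method="bootstrap" (default): seeded nonparametric bootstrap of the
    median difference with a normal-approximation p-value; in seeded null
    calibrations its type-I error sits at the nominal 5%.
    method="quantreg": intercept-only quantile regression at the median
    with heteroskedasticity-robust (Greene sandwich) standard errors; this
    route is noticeably conservative at moderate n, which is why it is not
    the default.  It falls back to the bootstrap if the fit degenerates.
    All-zero differences return p = 1, flagged.
    """
    diff = absolute_bias(pair)
    med = float(np.median(diff))
    if np.all(diff == 0.0):
        return MedianDifferenceResult(med, 1.0, "degenerate", degenerate=True)
    if len(diff) < 10:
        raise ValidationError("need n >= 10 for median-difference inference")
    if method not in ("bootstrap", "quantreg"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "quantreg":
        try:
            import statsmodels.api as sm
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.QuantReg(diff, np.ones((len(diff), 1)))
                fit = model.fit(q=0.5)
                se = float(fit.bse[0])
                est = float(fit.params[0])
            if np.isfinite(se) and se > 0:
                z = est / se
                p = 2.0 * stats.norm.sf(abs(z))
                return MedianDifferenceResult(med, float(p), "quantreg_robust")
        except Exception:
            pass
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
    boot = np.median(diff[idx], axis=1)
    se = float(boot.std(ddof=1))
    if se == 0.0:
        # zero resampling variance: a constant non-zero shift is maximally
        # significant, a constant zero shift is null
        return MedianDifferenceResult(med, 1.0 if med == 0.0 else 0.0, "bootstrap",
                                      degenerate=True)
    p = 2.0 * stats.norm.sf(abs(med / se))
    return MedianDifferenceResult(med, float(p), "bootstrap")


# --------------------------------------------------------------------------
# per-equation x per-stratum reports
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy of one equation in one group (one row of the results table)."""

    equation_id: str
    group: str              # stratum label or "all children"
    n: int
    bias_median: float
    bias_q25: float
    bias_q75: float
    pct_bias_median: float
    pct_bias_q25: float
    pct_bias_q75: float
    mape_mean: float
    ccf_count: int
    ccf_fraction: float
    ccf_ci_low: float
    ccf_ci_high: float


def _report_for(pair: PairedSeries, eq_id: str, group: str, config: StudyConfig) -> AccuracyReport:
    bias = absolute_bias(pair)
    pct = percent_bias(pair)
    b50, b25, b75 = median_iqr(bias)
    p50, p25, p75 = median_iqr(pct)
    count, frac = ccf(pair, config.ccf_threshold_pct)
    low, high = clopper_pearson(count, len(pair), config.ci_level)
    return AccuracyReport(
        equation_id=eq_id, group=group, n=len(pair),
        bias_median=b50, bias_q25=b25, bias_q75=b75,
        pct_bias_median=p50, pct_bias_q25=p25, pct_bias_q75=p75,
        mape_mean=mape(pair),
        ccf_count=count, ccf_fraction=frac, ccf_ci_low=low, ccf_ci_high=high,
    )


def build_report(
    eree_table: pd.DataFrame,
    cohort: Sequence[Subject],
    config: StudyConfig | None = None,
) -> list[AccuracyReport]:
    """One AccuracyReport per equation x (four strata + all children).

    eree_table is the evaluate_all output (rows indexed by subject id,
    one column per equation).  Every subject must carry mree_kcal_d and a
    derived weight_status.
    """
    config = config or StudyConfig()
    missing = [s.id for s in cohort if s.mree_kcal_d is None]
    if missing:
        raise StageError(
            f"{len(missing)} subject(s) lack measured REE (e.g. {missing[:5]}); "
            "run the measurement stage first"
        )
    by_id = {s.id: s for s in cohort}
    if not set(by_id) <= set(eree_table.index):
        raise StageError("eree table does not cover every subject")

    groups: list[tuple[str, list[Subject]]] = []
    strata: dict[Stratum, list[Subject]] = {st: [] for st in STRATA}
    for s in cohort:
        strata[s.stratum].append(s)
    for st in STRATA:
        groups.append((st.label, strata[st]))
    groups.append((ALL_CHILDREN, list(cohort)))

    reports: list[AccuracyReport] = []
    for eq_id in eree_table.columns:
        for label, members in groups:
            if not members:
                continue
            ids = [s.id for s in members]
            pair = PairedSeries(
                mree=np.array([by_id[i].mree_kcal_d for i in ids]),
                eree=eree_table.loc[ids, eq_id].to_numpy(float),
            )
            reports.append(_report_for(pair, eq_id, label, config))
    return reports


def report_frame(reports: Sequence[AccuracyReport]) -> pd.DataFrame:
    """Reports as a tidy DataFrame (full precision, one row per report)."""
    return pd.DataFrame([r.__dict__ for r in reports])


def render_report(reports: Sequence[AccuracyReport], decimals_pct: int = 1) -> pd.DataFrame:
    """Display-rounded table: integer kcal biases, one-decimal percents,
    two-decimal CI bounds (half-up)."""
    rows = []
    for r in reports:
        rows.append({
            "equation_id": r.equation_id,
            "group": r.group,
            "n": r.n,
            "bias_kcal_d": f"{round_half_up(r.bias_median):.0f} "
                           f"({round_half_up(r.bias_q25):.0f}; {round_half_up(r.bias_q75):.0f})",
            "bias_pct": f"{round_half_up(r.pct_bias_median):.0f} "
                        f"({round_half_up(r.pct_bias_q25):.0f}; {round_half_up(r.pct_bias_q75):.0f})",
            "mape_pct": f"{round_half_up(r.mape_mean):.0f}",
            "ccf": f"{r.ccf_count} ({round_half_up(100 * r.ccf_fraction, decimals_pct):.{decimals_pct}f}%)",
            "ccf_ci": f"{round_half_up(r.ccf_ci_low, 2):.2f} to {round_half_up(r.ccf_ci_high, 2):.2f}",
        })
    return pd.DataFrame(rows)
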