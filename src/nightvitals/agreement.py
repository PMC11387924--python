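"""Method-agreement statistics for device-versus-reference comparisons.

Implements the full suite used to validate epoch-gridded vital-sign
monitors against polysomnography: Bland-Altman bias and limits of
agreement (LoA) with parametric confidence intervals, the minimum
detectable change MDC = (LoA_upper - LoA_lower) / 2, mean absolute error
(MAE) and mean absolute percentage error (MAPE), the standardized
absolute difference (a directionless Cohen's d), the single-measure
absolute-agreement intraclass correlation ICC(2,1) from two-way
random-effects ANOVA mean squares with an F-based confidence interval,
simple-regression r², the Matthews correlation coefficient for 2x2
confusion matrices, and empirical absolute-error quantiles/CDFs.

The object interface follows the fitted-model convention: build a
:class:`PairedAgreement` from paired measurements, call :meth:`fit`, and
read estimates, intervals and the ``summary()`` table off the returned
:class:`AgreementResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError, UndefinedResultError
from .harmonize import PairedEpochs

#: Default limits-of-agreement multiplier (normal 95% band).
LOA_MULTIPLIER = 1.96


def mdc_from_sd(sd_diff: float, loa_multiplier: float = LOA_MULTIPLIER) -> float:
    """Minimum detectable change from the SD of paired differences.

    With LoA = bias ± m·sd, the agreement width is 2·m·sd and
    MDC = (LoA_upper - LoA_lower) / 2 = m·sd.
    """
    return loa_multiplier * sd_diff


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    bias_ci: Tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: Tuple[float, float]
    loa_upper_ci: Tuple[float, float]
    mdc: float


def bland_altman(device: np.ndarray, reference: Optional[np.ndarray] = None,
                 ci_level: float = 0.95,
                 loa_multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Pass paired vectors, or a single vector of differences (device minus
    reference). The bias CI uses SE = sd/sqrt(n) with a t quantile; each
    LoA bound's CI uses the classical SE = sd·sqrt(3/n).
    """
    d = np.asarray(device, dtype=float)
    if reference is not None:
        r = np.asarray(reference, dtype=float)
        if r.shape != d.shape:
            raise InputError("device and reference must have equal length")
        d = d - r
    n = d.size
    if n < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = stats.t.ppf(0.5 + ci_level / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    lo = bias - loa_multiplier * sd
    hi = bias + loa_multiplier * sd
    return BlandAltmanResult(
        n=n, bias=bias, sd_diff=sd,
        bias_ci=(bias - tq * se_bias, bias + tq * se_bias),
        loa_lower=lo, loa_upper=hi,
        loa_lower_ci=(lo - tq * se_loa, lo + tq * se_loa),
        loa_upper_ci=(hi - tq * se_loa, hi + tq * se_loa),
        mdc=mdc_from_sd(sd, loa_multiplier),
    )


def _t_interval(x: np.ndarray, ci_level: float) -> Tuple[float, float]:
    n = x.size
    if n < 2:
        return (float("nan"), float("nan"))
    m = x.mean()
    se = x.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + ci_level / 2, n - 1)
    return (float(m - tq * se), float(m + tq * se))


def mae_mape(device: np.ndarray, reference: np.ndarray,
             participant_ids: Optional[Sequence] = None,
             aggregate: str = "pooled", ci_level: float = 0.95
             ) -> Tuple[float, Tuple[float, float], float, Tuple[float, float]]:
    """Mean absolute error and mean absolute percentage error with CIs.

    ``aggregate="pooled"`` computes MAE/MAPE over all pairs with a t-based
    CI across pairs; ``"per_participant"`` computes per-participant values
    first, then the mean and t-based CI across participants (the
    appropriate scale for all-night summaries where the participant is the
    unit of replication).
    """
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape:
        raise InputError("device and reference must have equal length")
    if np.any(r <= 0):
        raise InputError("MAPE requires strictly positive reference values")
    abs_err = np.abs(d - r)
    pct_err = abs_err / r * 100.0
    if aggregate == "pooled":
        return (float(abs_err.mean()), _t_interval(abs_err, ci_level),
                float(pct_err.mean()), _t_interval(pct_err, ci_level))
    if aggregate != "per_participant":
        raise InputError("aggregate must be 'pooled' or 'per_participant'")
    if participant_ids is None:
        raise InputError("per_participant aggregation needs participant_ids")
    ids = np.asarray(participant_ids)
    uniq = np.unique(ids)
    maes = np.array([abs_err[ids == u].mean() for u in uniq])
    mapes = np.array([pct_err[ids == u].mean() for u in uniq])
    return (float(maes.mean()), _t_interval(maes, ci_level),
            float(mapes.mean()), _t_interval(mapes, ci_level))


def sad(device: np.ndarray, reference: np.ndarray,
        denominator: str = "pooled") -> float:
    """Standardized absolute difference: a directionless Cohen's d.

    ``denominator="pooled"`` divides |mean difference| by the pooled SD of
    the two samples (textbook Cohen's d); ``"diff"`` divides by the SD of
    the paired differences instead.
    """
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.size < 2 or r.size < 2:
        raise InsufficientDataError("SAD needs at least 2 values per group")
    num = abs(d.mean() - r.mean())
    if denominator == "pooled":
        s2 = (((d.size - 1) * d.var(ddof=1) + (r.size - 1) * r.var(ddof=1))
              / (d.size + r.size - 2))
        denom = np.sqrt(s2)
    elif denominator == "diff":
        if d.shape != r.shape:
            raise InputError("'diff' denominator needs paired samples")
        denom = (d - r).std(ddof=1)
    else:
        raise InputError("denominator must be 'pooled' or 'diff'")
    if denom == 0:
        if num == 0:
            return 0.0
        raise UndefinedResultError("zero SD with nonzero mean difference")
    return float(num / denom)


@dataclass(frozen=True)
class ICCResult:
    icc: float            # reported value, clamped to [0, 1]
    icc_raw: float        # unclamped estimate
    ci: Tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_two_way_random(ratings: np.ndarray, ci_level: float = 0.95) -> ICCResult:
    """Single-measure absolute-agreement ICC(2,1) for an n x 2 matrix.

    Computed from two-way random-effects ANOVA mean squares; the
    confidence interval follows the F-distribution method of McGraw and
    Wong. The reported value is clamped to [0, 1]; the raw estimate is
    retained on the result.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise InputError("ratings must be an n x 2 matrix (device, reference)")
    n, k = y.shape
    if n < 5:
        raise InsufficientDataError("ICC needs at least 5 subjects")
    if np.any(np.isnan(y)):
        raise InputError("ratings must be complete")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(0.0, ss_err) / ((n - 1) * (k - 1))

    if mse == 0 and msc == 0:
        # perfect agreement (or perfectly degenerate): ICC 1 when subjects
        # vary, undefined->0 when nothing varies
        if msr > 0:
            return ICCResult(1.0, 1.0, (1.0, 1.0), msr, msc, mse)
        warnings.warn("zero between-subject variance; ICC reported as 0")
        return ICCResult(0.0, 0.0, (0.0, 0.0), msr, msc, mse)

    icc_raw = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if msr <= mse:
        warnings.warn("between-subject variance does not exceed error variance;"
                      " ICC clamped to 0")
    icc = float(np.clip(icc_raw, 0.0, 1.0))

    # McGraw-Wong CI for ICC(2,1)
    alpha = 1 - ci_level
    a = icc_raw
    fj = msc / mse if mse > 0 else np.inf
    if np.isfinite(fj):
        vn = (k - 1) * (n - 1) * (k * a * fj + n * (1 + (k - 1) * a) - k * a) ** 2
        vd = ((n - 1) * k ** 2 * a ** 2 * fj ** 2
              + (n * (1 + (k - 1) * a) - k * a) ** 2)
        v = max(1.0, vn / vd) if vd > 0 else 1.0
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse)
                                         + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse
                                         + n * f_u * msr)
        ci = (float(np.clip(lower, 0.0, 1.0)), float(np.clip(upper, 0.0, 1.0)))
    else:
        ci = (icc, icc)
    return ICCResult(icc, float(icc_raw), ci, msr, msc, mse)


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    slope: float
    intercept: float


def r_squared(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Coefficient of determination from simple linear regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("regression needs at least 3 points")
    if np.var(x) == 0:
        raise InputError("x must not be constant")
    fit = stats.linregress(x, y)
    return RegressionResult(r2=float(fit.rvalue ** 2), slope=float(fit.slope),
                            intercept=float(fit.intercept))


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Binary classification counts (device prediction vs reference truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def mcc(cm: ConfusionMatrix2x2) -> float:
    """Matthews correlation coefficient; any zero denominator factor -> 0."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    tp, fp, fn, tn = (float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def abs_error_quantiles(device: np.ndarray, reference: np.ndarray,
                        probs: Sequence[float] = (0.5, 0.9)
                        ) -> Tuple[Dict[float, float], np.ndarray, np.ndarray]:
    """Empirical quantiles and CDF of the absolute differences.

    Quantiles use linear interpolation between order statistics. Returns
    ``(quantiles, sorted_abs_errors, cdf_probs)`` where the last two trace
    the empirical CDF.
    """
    d = np.abs(np.asarray(device, dtype=float) - np.asarray(reference, dtype=float))
    if d.size < 1:
        raise InsufficientDataError("need at least one pair")
    qs = {float(p): float(np.quantile(d, p, method="linear")) for p in probs}
    x = np.sort(d)
    cdf = np.arange(1, d.size + 1) / d.size
    return qs, x, cdf


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """All agreement statistics for one device/variable/stratum."""

    n_pairs: int
    device_mean: float
    device_sd: float
    reference_mean: float
    reference_sd: float
    bias: float
    sd_diff: float
    bias_ci: Tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: Tuple[float, float]
    loa_upper_ci: Tuple[float, float]
    mdc: float
    mae: float
    mae_ci: Tuple[float, float]
    mape_pct: float
    mape_ci: Tuple[float, float]
    sad: float
    sad_ci: Tuple[float, float]
    icc: float
    icc_ci: Tuple[float, float]
    r2: float
    variable: str = "hr"
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd_diff > 0 and not self.loa_lower < self.loa_upper:
            raise InputError("LoA bounds out of order")
        if abs(self.mdc - (self.loa_upper - self.loa_lower) / 2) > 1e-9:
            raise InputError("MDC must equal half the agreement width")
        if self.mae < abs(self.bias) - 1e-9:
            raise InputError("MAE cannot be smaller than |bias|")
        if np.isfinite(self.icc) and not -1e-9 <= self.icc <= 1 + 1e-9:
            raise InputError("reported ICC must lie in [0, 1]")

    def to_dict(self) -> Dict[str, object]:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


class PairedAgreement:
    """Agreement model for paired device/reference measurements.

    Parameters
    ----------
    device, reference : array-like
        Equal-length paired measurements (epoch values or nightly means).
    participant_ids : sequence, optional
        Grouping labels enabling per-participant aggregation of MAE/MAPE.
    stage_labels : sequence, optional
        Reference vigilance stage per pair (carried through for
        stratification, not used by ``fit`` itself).
    """

    def __init__(self, device, reference, participant_ids=None,
                 stage_labels=None, variable: str = "hr", unit: str = "",
                 label: str = ""):
        self.device = np.asarray(device, dtype=float)
        self.reference = np.asarray(reference, dtype=float)
        if self.device.shape != self.reference.shape:
            raise InputError("device and reference must have equal length")
        if np.any(np.isnan(self.device)) or np.any(np.isnan(self.reference)):
            raise InputError("pairs must be complete; drop missing epochs first")
        self.participant_ids = (None if participant_ids is None
                                else np.asarray(participant_ids))
        self.stage_labels = (None if stage_labels is None
                             else np.asarray(stage_labels, dtype=object))
        self.variable = variable
        self.unit = unit or ("bpm" if variable == "hr" else "cpm")
        self.label = label

    @classmethod
    def from_pairs(cls, pairs: PairedEpochs, label: str = "") -> "PairedAgreement":
        ids = np.repeat(pairs.participant_id, len(pairs))
        return cls(pairs.device_values, pairs.reference_values,
                   participant_ids=ids, stage_labels=pairs.stage_labels,
                   variable=pairs.variable, label=label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, device_col: str = "device",
                       reference_col: str = "reference",
                       participant_col: Optional[str] = "participant_id",
                       stage_col: Optional[str] = None,
                       variable: str = "hr", label: str = "") -> "PairedAgreement":
        ids = (df[participant_col].to_numpy()
               if participant_col and participant_col in df else None)
        stages = df[stage_col].to_numpy() if stage_col and stage_col in df else None
        return cls(df[device_col].to_numpy(), df[reference_col].to_numpy(),
                   participant_ids=ids, stage_labels=stages,
                   variable=variable, label=label)

    def fit(self, aggregate: str = "pooled", ci_level: float = 0.95,
            loa_multiplier: float = LOA_MULTIPLIER,
            sad_denominator: str = "pooled",
            n_boot: int = 500, boot_seed: int = 0) -> "AgreementResults":
        """Compute the full agreement suite.

        ``aggregate`` controls MAE/MAPE pooling (see :func:`mae_mape`); the
        SAD confidence interval is obtained by a seeded nonparametric
        bootstrap over pairs.
        """
        d, r = self.device, self.reference
        n = d.size
        ba = bland_altman(d, r, ci_level=ci_level, loa_multiplier=loa_multiplier)
        mae, mae_ci, mape, mape_ci = mae_mape(
            d, r, participant_ids=self.participant_ids,
            aggregate=aggregate, ci_level=ci_level)
        sad_val = sad(d, r, denominator=sad_denominator)
        rng = np.random.default_rng(boot_seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                boots.append(sad(d[idx], r[idx], denominator=sad_denominator))
            except (UndefinedResultError, InsufficientDataError):
                continue
        if boots:
            sad_ci = (float(np.quantile(boots, (1 - ci_level) / 2)),
                      float(np.quantile(boots, 0.5 + ci_level / 2)))
        else:
            sad_ci = (sad_val, sad_val)
        try:
            icc_res = icc_two_way_random(np.column_stack([d, r]),
                                         ci_level=ci_level)
        except InsufficientDataError:
            # reliability is not estimable below 5 subjects; keep the rest
            nan = float("nan")
            icc_res = ICCResult(nan, nan, (nan, nan), nan, nan, nan)
        try:
            reg = r_squared(r, d)
            r2 = reg.r2
        except InputError:
            reg = RegressionResult(float("nan"), float("nan"), float("nan"))
            r2 = float("nan")
        report = AgreementReport(
            n_pairs=n,
            device_mean=float(d.mean()), device_sd=float(d.std(ddof=1)),
            reference_mean=float(r.mean()), reference_sd=float(r.std(ddof=1)),
            bias=ba.bias, sd_diff=ba.sd_diff, bias_ci=ba.bias_ci,
            loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
            loa_lower_ci=ba.loa_lower_ci, loa_upper_ci=ba.loa_upper_ci,
            mdc=ba.mdc, mae=mae, mae_ci=mae_ci, mape_pct=mape, mape_ci=mape_ci,
            sad=sad_val, sad_ci=sad_ci, icc=icc_res.icc, icc_ci=icc_res.ci,
            r2=r2, variable=self.variable, unit=self.unit, label=self.label)
        return AgreementResults(self, report, icc_res, reg)


class AgreementResults:
    """Fitted agreement statistics with a summary table and diagnostics."""

    def __init__(self, model: PairedAgreement, report: AgreementReport,
                 icc_result: ICCResult, regression: RegressionResult):
        self.model = model
        self.report = report
        self.icc_result = icc_result
        self.regression = regression

    def __getattr__(self, name):
        # delegate statistic lookups to the report
        report = self.__dict__.get("report")
        if report is not None and hasattr(report, name):
            return getattr(report, name)
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.report.to_dict()])

    def summary(self) -> str:
        r = self.report
        u = r.unit
        lines = [
            f"Paired agreement ({r.variable}, {u})"
            + (f" — {r.label}" if r.label else ""),
            "=" * 54,
            f"n pairs               {r.n_pairs}",
            f"device mean (SD)      {r.device_mean:.2f} ({r.device_sd:.2f}) {u}",
            f"reference mean (SD)   {r.reference_mean:.2f} ({r.reference_sd:.2f}) {u}",
            f"bias (SD)             {r.bias:.2f} ({r.sd_diff:.2f}) "
            f"[{r.bias_ci[0]:.2f}, {r.bias_ci[1]:.2f}]",
            f"LoA lower             {r.loa_lower:.2f} "
            f"[{r.loa_lower_ci[0]:.2f}, {r.loa_lower_ci[1]:.2f}]",
            f"LoA upper             {r.loa_upper:.2f} "
            f"[{r.loa_upper_ci[0]:.2f}, {r.loa_upper_ci[1]:.2f}]",
            f"MDC                   {r.mdc:.2f} {u}",
            f"MAE                   {r.mae:.2f} [{r.mae_ci[0]:.2f}, {r.mae_ci[1]:.2f}]",
            f"MAPE                  {r.mape_pct:.2f}% "
            f"[{r.mape_ci[0]:.2f}, {r.mape_ci[1]:.2f}]",
            f"SAD                   {r.sad:.2f} [{r.sad_ci[0]:.2f}, {r.sad_ci[1]:.2f}]",
            f"ICC(2,1)              {r.icc:.2f} [{r.icc_ci[0]:.2f}, {r.icc_ci[1]:.2f}]",
            f"r^2                   {r.r2:.2f}",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None):
        """Bland-Altman scatter: pair means vs differences with bias/LoA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = (self.model.device + self.model.reference) / 2
        d = self.model.device - self.model.reference
        r = self.report
        ax.scatter(m, d, s=8, alpha=0.5)
        ax.axhline(r.bias, color="k", lw=1)
        for y in (r.loa_lower, r.loa_upper):
            ax.axhline(y, color="k", lw=1, ls="--")
        ax.set_xlabel(f"mean of methods ({r.unit})")
        ax.set_ylabel(f"device - reference ({r.unit})")
        return ax


# ---------------------------------------------------------------------------
# Report serialization helpers
# ---------------------------------------------------------------------------

def _fmt_pair(value: float, sd: float) -> str:
    return f"{value:.2f} ({sd:.2f})"


def _fmt_ci(value: float, ci: Tuple[float, float]) -> str:
    return f"{value:.2f} ({ci[0]:.2f} to {ci[1]:.2f})"


def table1_row(report: AgreementReport) -> Dict[str, str]:
    """One row of the all-night summary table, with the conventional
    'value (lower to upper)' formatting."""
    return {
        "device_mean_sd": _fmt_pair(report.device_mean, report.device_sd),
        "psg_mean_sd": _fmt_pair(report.reference_mean, report.reference_sd),
        "bias_sd_ci": (f"{report.bias:.2f} ({report.sd_diff:.2f}; "
                       f"{report.bias_ci[0]:.2f} to {report.bias_ci[1]:.2f})"),
        "loa_lower_ci": _fmt_ci(report.loa_lower, report.loa_lower_ci),
        "loa_upper_ci": _fmt_ci(report.loa_upper, report.loa_upper_ci),
        "mdc": f"{report.mdc:.2f}",
        "mae_ci": _fmt_ci(report.mae, report.mae_ci),
        "sad_ci": _fmt_ci(report.sad, report.sad_ci),
        "mape_ci": _fmt_ci(report.mape_pct, report.mape_ci),
        "icc_ci": _fmt_ci(report.icc, report.icc_ci),
    }


TABLE1_COLUMNS = ["device_mean_sd", "psg_mean_sd", "bias_sd_ci", "loa_lower_ci",
                  "loa_upper_ci", "mdc", "mae_ci", "sad_ci", "mape_ci", "icc_ci"]


def reports_to_table(reports: Dict[str, AgreementReport]) -> pd.DataFrame:
    """Stack labelled reports into an all-night-summary-shaped table."""
    rows = {label: table1_row(rep) for label, rep in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=TABLE1_COLUMNS)
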