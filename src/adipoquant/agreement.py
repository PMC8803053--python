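"""Inter-method agreement statistics.

Implements the three analyses used to validate one morphometry pipeline
against another on paired per-sample measurements:

* **ICC(C,1)** — intraclass correlation under a two-way mixed-effects model
  aimed at consistency, single measures: with subjects as rows and methods as
  columns of an n×k table, the two-way ANOVA gives the between-subject mean
  square MSR and residual mean square MSE, and

      ICC(C,1) = (MSR − MSE) / (MSR + (k − 1)·MSE).

  The 95% CI follows the classical F-based construction: with
  F = MSR/MSE on (n−1, (n−1)(k−1)) degrees of freedom,
  lower = (F/F₁₋α⁄₂ − 1)/(F/F₁₋α⁄₂ + k − 1) and the upper bound uses the
  reciprocal quantile. The F test is the upper-tail test of ICC = 0.
  Consistency ICC ignores a fixed offset between methods by construction.

* **Bland–Altman** — per-subject differences d = A − B summarised by their
  mean, sample SD and limits of agreement mean ± 1.96·SD, plus the
  (mean, difference) point table for plotting.

* **Paired OLS regression** of method B on method A with Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "DegenerateDataError",
    "icc_consistency",
    "icc_absolute_agreement",
    "bland_altman",
    "paired_regression",
    "analyze_agreement",
    "read_paired_csv",
    "reliability_label",
]

LOA_MULTIPLIER = 1.96


class DegenerateDataError(ValueError):
    """All measurements identical: ICC undefined (no variance to partition)."""


@dataclass
class PairedMeasurements:
    """Paired per-subject values from two methods (missing rows dropped upstream)."""

    subject_ids: list
    method_a: np.ndarray
    method_b: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if not (len(self.subject_ids) == len(self.method_a) == len(self.method_b)):
            raise ValueError("subject_ids, method_a, method_b must be equal length")
        if len(self.method_a) < 2:
            raise ValueError("at least 2 paired subjects are required")
        if np.isnan(self.method_a).any() or np.isnan(self.method_b).any():
            raise ValueError("missing values must be dropped before construction")

    @property
    def n(self) -> int:
        return len(self.method_a)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.method_a, self.method_b])


@dataclass
class AgreementResult:
    """Container for ICC, Bland–Altman and regression results of one variable."""

    variable_name: str = ""
    n: int = 0
    k: int = 2
    icc: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    f_stat: float = np.nan
    f_df1: float = np.nan
    f_df2: float = np.nan
    f_pvalue: float = np.nan
    reliability: str = ""
    mean_diff: float = np.nan
    sd_diff: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    r: float = np.nan
    ba_points: pd.DataFrame | None = field(default=None, repr=False)


def _two_way_anova(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects × raters) decomposition.

    Returns (MSR, MSC, MSE, n, k): between-subjects, between-raters and
    residual mean squares.
    """
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_total = float(((matrix - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def reliability_label(ci_low: float) -> str:
    """Qualitative reliability by the lower CI bound: ≥0.90 excellent,
    ≥0.75 good, ≥0.50 moderate, else poor."""
    if np.isnan(ci_low):
        return ""
    if ci_low >= 0.90:
        return "excellent"
    if ci_low >= 0.75:
        return "good"
    if ci_low >= 0.50:
        return "moderate"
    return "poor"


def icc_consistency(
    data: PairedMeasurements, alpha: float = 0.05
) -> AgreementResult:
    """ICC(C,1): two-way mixed effects, consistency, single measures."""
    matrix = data.as_matrix()
    msr, _, mse, n, k = _two_way_anova(matrix)
    if np.ptp(matrix) == 0:
        raise DegenerateDataError(
            "all measurements identical; ICC undefined (zero subject and "
            "residual variance)"
        )
    if msr == 0 and mse == 0:
        raise DegenerateDataError("zero between-subject and residual variance")
    icc = (msr - mse) / (msr + (k - 1) * mse) if (msr + (k - 1) * mse) > 0 else np.nan
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    if mse == 0:
        f_obs, ci_low, ci_high, pvalue = np.inf, icc, icc, 0.0
    else:
        f_obs = msr / mse
        fq = stats.f.ppf(1 - alpha / 2, df1, df2)
        fq_rev = stats.f.ppf(1 - alpha / 2, df2, df1)
        fl = f_obs / fq
        fu = f_obs * fq_rev
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
        pvalue = float(stats.f.sf(f_obs, df1, df2))
    return AgreementResult(
        variable_name=data.variable_name,
        n=n,
        k=k,
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        f_stat=float(f_obs),
        f_df1=df1,
        f_df2=df2,
        f_pvalue=pvalue,
        reliability=reliability_label(ci_low),
    )


def icc_absolute_agreement(
    data: PairedMeasurements, alpha: float = 0.05
) -> AgreementResult:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    Provided for completeness; sensitive to fixed offsets, unlike ICC(C,1).
    CI by the Satterthwaite approximation of McGraw & Wong.
    """
    matrix = data.as_matrix()
    msr, msc, mse, n, k = _two_way_anova(matrix)
    if np.ptp(matrix) == 0:
        raise DegenerateDataError("all measurements identical; ICC undefined")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else np.nan
    if mse == 0:
        return AgreementResult(
            variable_name=data.variable_name, n=n, k=k, icc=float(icc),
            ci_low=float(icc), ci_high=float(icc), f_stat=np.inf,
            f_df1=n - 1, f_df2=(n - 1) * (k - 1), f_pvalue=0.0,
            reliability=reliability_label(icc),
        )
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    fj = msr / mse
    ci_low = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_star2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star2 * msr
    )
    return AgreementResult(
        variable_name=data.variable_name, n=n, k=k, icc=float(icc),
        ci_low=float(ci_low), ci_high=float(ci_high), f_stat=float(fj),
        f_df1=n - 1, f_df2=(n - 1) * (k - 1),
        f_pvalue=float(stats.f.sf(fj, n - 1, (n - 1) * (k - 1))),
        reliability=reliability_label(ci_low),
    )


def bland_altman(data: PairedMeasurements) -> AgreementResult:
    """Bland–Altman: mean difference (A − B), sample SD, limits of agreement,
    and the per-subject (mean, difference) plotting table."""
    d = data.method_a - data.method_b
    m = (data.method_a + data.method_b) / 2.0
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    points = pd.DataFrame(
        {"subject_id": data.subject_ids, "mean": m, "difference": d}
    )
    return AgreementResult(
        variable_name=data.variable_name,
        n=data.n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        ba_points=points,
    )


def paired_regression(data: PairedMeasurements) -> tuple[float, float, float]:
    """OLS of method B on method A; returns (slope, intercept, Pearson r)."""
    if data.n < 3:
        raise ValueError("regression needs at least 3 paired subjects")
    if np.var(data.method_a) == 0:
        raise ValueError("zero-variance predictor (method A is constant)")
    res = stats.linregress(data.method_a, data.method_b)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def analyze_agreement(data: PairedMeasurements, alpha: float = 0.05) -> AgreementResult:
    """One-call combination: ICC(C,1) + Bland–Altman + regression."""
    out = icc_consistency(data, alpha=alpha)
    ba = bland_altman(data)
    out.mean_diff, out.sd_diff = ba.mean_diff, ba.sd_diff
    out.loa_low, out.loa_high = ba.loa_low, ba.loa_high
    out.ba_points = ba.ba_points
    if data.n >= 3 and np.var(data.method_a) > 0:
        out.slope, out.intercept, out.r = paired_regression(data)
    return out


def read_paired_csv(path: str | Path, variable: str | None = None) -> PairedMeasurements:
    """Load paired measurements from CSV.

    Wide layout: columns ``subject_id, a_value, b_value``. Long layout:
    columns ``subject_id, method, variable, value`` with exactly two methods;
    ``variable`` selects the row subset. Rows with missing values are dropped
    (listwise) with a note printed when any are removed.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"subject_id", "a_value", "b_value"} <= cols:
        wide = df[["subject_id", "a_value", "b_value"]]
        name = variable or ""
    elif {"subject_id", "method", "value"} <= cols:
        sub = df
        if variable is not None and "variable" in cols:
            sub = df[df["variable"] == variable]
        methods = sorted(sub["method"].unique())
        if len(methods) != 2:
            raise ValueError(f"expected exactly 2 methods, found {methods}")
        wide = sub.pivot_table(
            index="subject_id", columns="method", values="value", aggfunc="first"
        ).reset_index()
        wide.columns = ["subject_id", "a_value", "b_value"]
        name = variable or ""
    else:
        raise ValueError(
            "CSV must have columns subject_id,a_value,b_value (wide) or "
            "subject_id,method[,variable],value (long)"
        )
    before = len(wide)
    wide = wide.dropna()
    dropped = before - len(wide)
    if dropped:
        print(f"read_paired_csv: dropped {dropped} row(s) with missing values")
    return PairedMeasurements(
        subject_ids=wide["subject_id"].tolist(),
        method_a=wide["a_value"].to_numpy(),
        method_b=wide["b_value"].to_numpy(),
        variable_name=name,
    )


def result_to_frame(result: AgreementResult) -> pd.DataFrame:
    d = asdict(result)
    d.pop("ba_points")
    return pd.DataFrame([d])
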