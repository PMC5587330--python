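"""Method-agreement statistics between reference and MIGET-derived shunt.

The validation question is whether the inversion-derived shunt (MM-S) agrees
with the flow-derived reference shunt (IVLM-S).  Three classical tools:

* ordinary least squares of MM-S on IVLM-S, duplicates as individual points;
* Bland-Altman analysis of the differences d = MM-S − IVLM-S, with limits of
  agreement at bias ± 2·SD (the study's convention, not 1.96·SD);
* duplicate coefficient of variation, pooled across settings as the
  root-mean-square of per-setting CVs, with settings whose duplicate mean is
  below a floor (default 0.01) excluded — at zero shunt a CV is meaningless.

Input is an "experiment table": one row per sample with columns
``perfusate, setting_id, duplicate, ivlm_shunt, mm_shunt`` (plus optional
``rss``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DataError

REQUIRED_COLUMNS = ("perfusate", "setting_id", "duplicate", "ivlm_shunt", "mm_shunt")


def validate_experiment_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"experiment table missing columns {missing}")
    if len(table) < 2:
        raise DataError("experiment table needs at least 2 rows")
    for col in ("ivlm_shunt", "mm_shunt"):
        v = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)) or np.any((v < 0) | (v > 1)):
            raise DataError(f"{col} must be finite fractions in [0, 1]")
    return table


@dataclass(frozen=True)
class AgreementReport:
    """Regression + Bland-Altman + duplicate-CV summary for one perfusate."""

    perfusate: str
    n_pairs: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bias: float
    sd_diff: float
    two_sd: float
    loa_low: float
    loa_high: float
    cv_overall: float | None  # percent; None if no eligible duplicate setting

    def summary(self) -> str:
        cv = "n/a" if self.cv_overall is None else f"{self.cv_overall:.1f}%"
        return "\n".join(
            [
                f"Agreement report ({self.perfusate}, n = {self.n_pairs} pairs)",
                "-----------------------------------------------",
                f"regression : MM-S = {self.slope:.3f} * IVLM-S + {self.intercept:+.3f}",
                f"             r^2 = {self.r_squared:.3f}  (p = {self.p_value:.2g})",
                f"Bland-Altman: bias = {self.bias:+.3f}, 2 SD = {self.two_sd:.3f}",
                f"             limits of agreement [{self.loa_low:+.3f}, {self.loa_high:+.3f}]",
                f"duplicate CV: {cv}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "perfusate": self.perfusate,
            "n_pairs": self.n_pairs,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "two_sd": self.two_sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "cv_overall": self.cv_overall,
        }


def ols_fit(table: pd.DataFrame) -> tuple[float, float, float, float]:
    """OLS of ``mm_shunt`` on ``ivlm_shunt`` over all rows.

    Duplicates enter as separate points.  Returns
    ``(slope, intercept, r_squared, p_value)`` where the p-value is for the
    slope.
    """
    validate_experiment_table(table)
    x = table["ivlm_shunt"].to_numpy(dtype=float)
    y = table["mm_shunt"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError("ivlm_shunt has zero variance; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(res.params[1]),
        float(res.params[0]),
        float(res.rsquared),
        float(res.pvalues[1]),
    )


def bland_altman(table: pd.DataFrame) -> tuple[float, float, float, float, float]:
    """Bland-Altman of d = MM-S − IVLM-S.

    Returns ``(bias, sd_diff, two_sd, loa_low, loa_high)``; the limits of
    agreement use bias ± 2·SD.  The sign convention means a negative bias
    reads as MM-S underestimating the reference shunt.
    """
    validate_experiment_table(table)
    d = (table["mm_shunt"] - table["ivlm_shunt"]).to_numpy(dtype=float)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, sd, 2 * sd, bias - 2 * sd, bias + 2 * sd


def duplicate_cv(table: pd.DataFrame, mean_floor: float = 0.01) -> float:
    """Overall duplicate coefficient of variation of MM-S, in percent.

    Per setting: CV = sample SD / mean of the duplicate ``mm_shunt`` values.
    Settings with fewer than 2 duplicates or a duplicate mean below
    ``mean_floor`` are excluded (CV diverges as the mean approaches zero).
    The overall figure pools per-setting CVs by root mean square.
    """
    validate_experiment_table(table)
    cvs = []
    for (_, _), grp in table.groupby(["perfusate", "setting_id"]):
        vals = grp["mm_shunt"].to_numpy(dtype=float)
        if vals.size < 2:
            continue
        mean = vals.mean()
        if mean < mean_floor:
            continue
        cvs.append(np.std(vals, ddof=1) / mean)
    if not cvs:
        raise DataError(
            "no setting with >= 2 duplicates and mean above the floor; "
            "duplicate CV undefined"
        )
    return float(np.sqrt(np.mean(np.square(cvs))) * 100.0)


def agreement_report(table: pd.DataFrame, perfusate: str | None = None) -> AgreementReport:
    """Full agreement summary for one perfusate's rows."""
    if perfusate is not None:
        table = table[table["perfusate"] == perfusate]
        if table.empty:
            raise DataError(f"no rows for perfusate {perfusate!r}")
    else:
        labels = table["perfusate"].unique()
        perfusate = labels[0] if len(labels) == 1 else "all"
    slope, intercept, r2, p = ols_fit(table)
    bias, sd, two_sd, lo, hi = bland_altman(table)
    try:
        cv = duplicate_cv(table)
    except DataError:
        cv = None
    return AgreementReport(
        perfusate=str(perfusate),
        n_pairs=len(table),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        bias=bias,
        sd_diff=sd,
        two_sd=two_sd,
        loa_low=lo,
        loa_high=hi,
        cv_overall=cv,
    )


def plot_agreement(table: pd.DataFrame, perfusate: str | None = None):
    """Scatter-with-regression and Bland-Altman panels; returns the figure."""
    import matplotlib.pyplot as plt

    if perfusate is not None:
        table = table[table["perfusate"] == perfusate]
    rep = agreement_report(table, None)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    x = table["ivlm_shunt"].to_numpy(dtype=float)
    y = table["mm_shunt"].to_numpy(dtype=float)
    ax1.plot(x, y, "o", ms=5)
    xx = np.linspace(0, max(1e-9, x.max()), 50)
    ax1.plot(xx, rep.slope * xx + rep.intercept, "-", label=(
        f"y = {rep.slope:.2f}x {rep.intercept:+.3f} (r$^2$={rep.r_squared:.2f})"))
    ax1.plot(xx, xx, "k--", lw=0.8, label="identity")
    ax1.set_xlabel("reference shunt (IVLM-S)")
    ax1.set_ylabel("derived shunt (MM-S)")
    ax1.legend(fontsize=8)

    mean = (x + y) / 2
    diff = y - x
    ax2.plot(mean, diff, "o", ms=5)
    for yv, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax2.axhline(yv, color="C1", ls=style, lw=1)
    ax2.set_xlabel("mean of methods")
    ax2.set_ylabel("MM-S − IVLM-S")
    ax2.set_title(f"bias {rep.bias:+.3f} ± {rep.two_sd:.3f} (2 SD)", fontsize=9)
    fig.suptitle(f"perfusate: {rep.perfusate}")
    fig.tight_layout()
    return fig
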