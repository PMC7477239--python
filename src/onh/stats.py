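"""Longitudinal analysis: monthly IOP aggregation, structural-change
statistics, group summaries, and primate-controlled partial correlation.

The partial correlation controls for the repeated-measures "primate effect"
by residualizing both variables on subject indicators (equivalently,
centring each within its subject), then taking the Pearson correlation of
the residuals.  The null hypothesis rho = 0 is tested with Fisher's
z-transform, ``z = atanh(rho) * sqrt(n - k - 3)`` with ``k = n_subjects - 1``
indicator covariates.  Group contrasts here use paired t-tests; a mixed
model would serve the same purpose but adds nothing to the quantities this
package reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import IOPSeries
from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
)

__all__ = [
    "MonthlyIOP",
    "ChangeStat",
    "PartialCorrelationResult",
    "SummaryStat",
    "monthly_aggregate",
    "oht_period_summary",
    "monthly_change",
    "group_summary",
    "partial_correlation",
    "fisher_z_test",
    "ARM_SELECTORS",
]


@dataclass(frozen=True)
class MonthlyIOP:
    month: int  # 0 = baseline
    mean_iop: float
    max_iop: float
    n_readings: int

    def __post_init__(self) -> None:
        if self.max_iop < self.mean_iop:
            raise ParameterError("monthly max IOP cannot be below the mean")


@dataclass(frozen=True)
class ChangeStat:
    interval: tuple[int, int]  # (m, m+1)
    mean_change: float  # metric units per month
    sd_change: float
    p_value: float
    n: int
    degenerate: bool = False  # all per-eye changes equal; p reported as 1


@dataclass(frozen=True)
class PartialCorrelationResult:
    rho_hat: float
    n_obs: int
    n_subjects: int
    df: int
    z_stat: float
    p_value: float
    saturated: bool = False  # |rho| = 1; p forced to 0


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: int

    def __iter__(self):
        return iter((self.mean, self.sd))


def monthly_aggregate(
    series: "IOPSeries | Mapping[int, float] | Sequence[float]",
    weeks_per_month: int = 4,
) -> list[MonthlyIOP]:
    """Collapse weekly readings into per-month mean and maximum IOP.

    Month ``m`` covers weeks ``(m-1)*wpm + 1 .. m*wpm``; week 0 (when
    present) becomes month 0 (baseline).  Months with no readings are
    omitted; partial months use whatever readings are present.
    """
    if weeks_per_month < 1:
        raise ParameterError("weeks_per_month must be >= 1")
    if isinstance(series, IOPSeries):
        readings = {w: float(v) for w, v in enumerate(series.weekly_iop)}
    elif isinstance(series, Mapping):
        readings = {int(w): float(v) for w, v in series.items()}
    else:
        readings = {i + 1: float(v) for i, v in enumerate(series)}
    if not readings:
        raise ParameterError("empty IOP series")

    by_month: dict[int, list[float]] = {}
    for week, value in sorted(readings.items()):
        month = 0 if week == 0 else (week - 1) // weeks_per_month + 1
        by_month.setdefault(month, []).append(value)
    return [
        MonthlyIOP(
            month=m,
            mean_iop=float(np.mean(vals)),
            max_iop=float(np.max(vals)),
            n_readings=len(vals),
        )
        for m, vals in sorted(by_month.items())
    ]


def oht_period_summary(
    monthly: Sequence[MonthlyIOP], from_month: int = 2, to_month: int = 7
) -> tuple[float, float]:
    """Average monthly mean and monthly maximum IOP over an OHT period.

    Defaults to months 2-7, the window over which the study reports the
    sustained-hypertension pressure of each eye.
    """
    window = [m for m in monthly if from_month <= m.month <= to_month]
    if not window:
        raise SelectionError(
            f"no monthly records in months {from_month}..{to_month}"
        )
    return (
        float(np.mean([m.mean_iop for m in window])),
        float(np.mean([m.max_iop for m in window])),
    )


ARM_SELECTORS = {
    "oht_right": lambda df: (df["treatment"] == "OHT") & (df["eye"] == "OD"),
    "oht_left": lambda df: (df["treatment"] == "OHT") & (df["eye"] == "OS"),
    "control": lambda df: df["treatment"] == "control",
}


def _arm_mask(cohort: pd.DataFrame, arm) -> pd.Series:
    if callable(arm):
        return arm(cohort)
    try:
        return ARM_SELECTORS[arm](cohort)
    except KeyError:
        raise SelectionError(
            f"unknown arm {arm!r}; known arms: {sorted(ARM_SELECTORS)}"
        ) from None


def monthly_change(
    cohort: pd.DataFrame, metric: str, arm="oht_right"
) -> list[ChangeStat]:
    """Per-interval change statistics of ``metric`` ('mrw' or 'lcd').

    For each month interval m -> m+1: per-eye difference, mean, sample SD
    (n-1), and a two-sided paired t-test against zero change.  When every
    per-eye change is identical (zero variance) the p-value is reported as
    1 by convention and flagged.
    """
    if metric not in ("mrw", "lcd"):
        raise ParameterError("metric must be 'mrw' or 'lcd'")
    sub = cohort[_arm_mask(cohort, arm)]
    if sub.empty:
        raise SelectionError(f"arm {arm!r} selects no rows")
    wide = sub.pivot_table(
        index=["primate_id", "eye"], columns="month", values=metric
    )
    months = sorted(wide.columns)
    if months != list(range(months[0], months[-1] + 1)):
        raise InsufficientDataError("months are not contiguous")
    if len(wide) < 2:
        raise InsufficientDataError("need at least 2 eyes in the arm")

    out: list[ChangeStat] = []
    for m in months[:-1]:
        diffs = (wide[m + 1] - wide[m]).dropna().to_numpy()
        if len(diffs) < 2:
            raise InsufficientDataError(
                f"need >= 2 paired observations for interval {m}->{m + 1}"
            )
        sd = float(np.std(diffs, ddof=1))
        if sd == 0.0:
            p, degenerate = 1.0, True
        else:
            p = float(sps.ttest_1samp(diffs, 0.0).pvalue)
            degenerate = False
        out.append(
            ChangeStat(
                interval=(m, m + 1),
                mean_change=float(diffs.mean()),
                sd_change=sd,
                p_value=p,
                n=len(diffs),
                degenerate=degenerate,
            )
        )
    return out


def group_summary(
    table: pd.DataFrame,
    column: str,
    group: int | None = None,
    eye: str | None = None,
    **filters,
) -> SummaryStat:
    """Mean and sample SD (ddof=1) of ``column`` over selected rows.

    ``group``/``eye`` and any further ``column=value`` filters restrict the
    rows; SD is reported as 0 for a single row.
    """
    sel = table
    conditions = dict(filters)
    if group is not None:
        conditions["group"] = group
    if eye is not None:
        conditions["eye"] = eye
    for key, value in conditions.items():
        if key not in sel.columns:
            raise SelectionError(f"no column {key!r} in table")
        sel = sel[sel[key] == value]
    if column not in table.columns:
        raise SelectionError(f"no column {column!r} in table")
    values = sel[column].dropna().to_numpy(float)
    if len(values) == 0:
        raise SelectionError("selection matched no rows")
    sd = 0.0 if len(values) == 1 else float(np.std(values, ddof=1))
    return SummaryStat(mean=float(values.mean()), sd=sd, n=len(values))


def _fisher_z(rho: float, n_obs: int, n_subjects: int) -> tuple[float, float, bool]:
    n_controls = n_subjects - 1
    dof = n_obs - n_controls - 3
    if dof < 1:
        raise InsufficientDataError("too few observations for the Fisher z test")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho), 0.0, True
    z = math.atanh(rho) * math.sqrt(dof)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, p, False


def partial_correlation(
    x: Sequence[float], y: Sequence[float], subject: Sequence
) -> PartialCorrelationResult:
    """Pearson partial correlation of x and y controlling for subject.

    Residualizes both variables on subject indicator variables -- i.e.
    centres each within its subject -- and correlates the residuals.
    ``df = n_obs - n_subjects - 1``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subject = np.asarray(subject)
    if not (len(x) == len(y) == len(subject)):
        raise ParameterError("x, y and subject must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("x and y must be finite")

    codes, _ = pd.factorize(subject)
    n_subjects = int(codes.max()) + 1
    rx = x - np.bincount(codes, weights=x)[codes] / np.bincount(codes)[codes]
    ry = y - np.bincount(codes, weights=y)[codes] / np.bincount(codes)[codes]
    if np.allclose(rx, 0.0) or np.allclose(ry, 0.0):
        raise DegenerateVarianceError(
            "zero within-subject variance; partial correlation undefined"
        )
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    n_obs = len(x)
    df = n_obs - n_subjects - 1
    if df < 1:
        raise InsufficientDataError("df = n_obs - n_subjects - 1 must be >= 1")
    z, p, saturated = _fisher_z(rho, n_obs, n_subjects)
    return PartialCorrelationResult(
        rho_hat=rho,
        n_obs=n_obs,
        n_subjects=n_subjects,
        df=df,
        z_stat=z,
        p_value=p,
        saturated=saturated,
    )


def fisher_z_test(result: PartialCorrelationResult) -> tuple[float, float]:
    """Fisher z statistic and two-sided normal p for rho = 0."""
    z, p, _ = _fisher_z(result.rho_hat, result.n_obs, result.n_subjects)
    return z, p
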