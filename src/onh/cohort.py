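"""Longitudinal ocular-hypertension cohort simulator.

Emulates the structure of a two-group primate microbead study: 10 primates
with unilateral OHT (right eye injected, left eye untreated control) and 6
with bilateral OHT, weekly rebound tonometry over 28 weeks, repeated
intracameral microbead injections, and monthly ONH morphometry (minimum rim
width, lamina cribrosa depth).

IOP model.  Each microbead injection obstructs outflow with a saturating
first-order time course: an injection at week ``w_i`` contributes
``injection_effect * (1 - exp(-(w - w_i)/tau))`` mmHg at week ``w``; the
summed response is capped at the group plateau.  An injection is scheduled
whenever the previous week's measured IOP sits below the group's
re-injection threshold (> 30 mmHg target for group 1, > 20 mmHg for group
2).  The delayed response is what makes induction take ~5-6 injections over
~4-5 weeks in both groups even though group 2's threshold is only a few
mmHg above baseline.  Weekly readings add noise whose SD grows with the
elevation above baseline (high-pressure eyes fluctuate strongly week to
week), on top of a small tonometry term (each reading is already the mean
of five rebound measurements).  Untreated fellow eyes show a consensual
rise (default +6 mmHg plateau, switchable off).

Structure model.  Monthly MRW/LCD increments are the sum of a deterministic
OHT effect concentrated in the month 1->2 interval (the generator
parameters, default -93 um MRW / +86 um LCD), an IOP-coupling term
``slope * (eye's monthly mean IOP - its arm's noise-free expected IOP)``,
and Gaussian noise.  Setting the month-1->2 means and the slopes to zero
with zero noise yields trajectories constant at baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "CohortParams",
    "IOPSeries",
    "simulate_iop_series",
    "detect_onset",
    "initial_injection_count",
    "generate_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "primate_id",
    "eye",
    "group",
    "treatment",
    "month",
    "mean_iop",
    "max_iop",
    "mrw",
    "lcd",
]


@dataclass(frozen=True)
class CohortParams:
    """Study-design and effect-size parameters of the simulated cohort.

    Pressure is in mmHg, structure in um, time in weeks/months.  Defaults
    reproduce the study conditions: baseline IOP ~13 mmHg, OHT plateaus of
    43 (group 1) and 31 (group 2) mmHg, re-injection below 30/20 mmHg,
    OHT onset = IOP > 20 mmHg on three consecutive weekly readings, and
    month-1->2 structural changes of -93 +/- 42 um (MRW) and +86 +/- 79.6 um
    (LCD) in OHT eyes.
    """

    n_group1: int = 10
    n_group2: int = 6
    baseline_iop_mean: float = 13.0
    baseline_iop_sd: float = 2.0
    tonometry_noise_sd: float = 1.0
    iop_fluctuation_cv: float = 0.25
    injection_effect: float = 6.0
    bead_response_tau: float = 2.5
    group1_plateau: float = 43.0
    group2_plateau: float = 31.0
    reinjection_threshold_g1: float = 30.0
    reinjection_threshold_g2: float = 20.0
    onset_threshold: float = 20.0
    onset_run_length: int = 3
    consensual_rise: bool = True
    consensual_rise_mmhg: float = 6.0
    consensual_rise_tau: float = 6.0
    study_weeks: int = 28
    weeks_per_month: int = 4
    baseline_mrw_mean: float = 278.8
    baseline_mrw_sd: float = 39.2
    baseline_lcd_mean: float = 203.0
    baseline_lcd_sd: float = 44.2
    mrw_change_m1m2_mean: float = -93.0
    mrw_change_m1m2_sd: float = 42.0
    lcd_change_m1m2_mean: float = 86.0
    lcd_change_m1m2_sd: float = 79.6
    mrw_drift_noise_sd: float = 25.0
    lcd_drift_noise_sd: float = 30.0
    iop_structure_slope_mrw: float = -2.0  # um per mmHg, negative: IOP thins the rim
    iop_structure_slope_lcd: float = 1.5  # um per mmHg, positive: IOP deepens the LC
    iop_structure_lag: int = 0  # months; 0 = concurrent-month coupling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ParameterError("each group needs at least one primate")
        if self.study_weeks < 1:
            raise ParameterError("study_weeks must be positive")
        if self.weeks_per_month < 1:
            raise ParameterError("weeks_per_month must be >= 1")
        if self.onset_run_length < 1:
            raise ParameterError("onset_run_length must be >= 1")
        if min(self.group1_plateau, self.group2_plateau, self.onset_threshold) <= 0:
            raise ParameterError("plateaus and thresholds must be positive")
        if min(self.reinjection_threshold_g1, self.reinjection_threshold_g2) <= 0:
            raise ParameterError("re-injection thresholds must be positive")
        for name in (
            "baseline_iop_sd",
            "tonometry_noise_sd",
            "iop_fluctuation_cv",
            "baseline_mrw_sd",
            "baseline_lcd_sd",
            "mrw_change_m1m2_sd",
            "lcd_change_m1m2_sd",
            "mrw_drift_noise_sd",
            "lcd_drift_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.bead_response_tau <= 0:
            raise ParameterError("bead_response_tau must be positive")
        if self.iop_structure_lag < 0:
            raise ParameterError("iop_structure_lag must be >= 0")

    def plateau(self, group: int) -> float:
        return self.group1_plateau if group == 1 else self.group2_plateau

    def reinjection_threshold(self, group: int) -> float:
        return (
            self.reinjection_threshold_g1
            if group == 1
            else self.reinjection_threshold_g2
        )


@dataclass(frozen=True)
class IOPSeries:
    """Weekly tonometry of one eye; index 0 is the baseline visit."""

    primate_id: str
    eye: str  # OD / OS
    treatment: str  # OHT / control
    weekly_iop: np.ndarray  # length study_weeks + 1
    injection_weeks: tuple[int, ...]
    onset_week: int | None
    baseline_iop: float  # true (noise-free) baseline level

    def __post_init__(self) -> None:
        object.__setattr__(self, "weekly_iop", np.asarray(self.weekly_iop, float))
        if np.any(self.weekly_iop <= 0):
            raise ParameterError("weekly IOP values must be positive")
        weeks = set(range(1, len(self.weekly_iop)))
        if not set(self.injection_weeks) <= weeks:
            raise ParameterError("injection weeks outside the observed weeks")


def detect_onset(
    series: "IOPSeries | Sequence[float]",
    threshold: float = 20.0,
    run_length: int = 3,
) -> int | None:
    """First week starting a run of ``run_length`` readings above ``threshold``.

    Weeks are 1-based: for an :class:`IOPSeries` the baseline reading (index
    0) is excluded; for a bare sequence, element ``i`` is week ``i + 1``.
    Returns ``None`` when no qualifying run exists.
    """
    if run_length < 1:
        raise ParameterError("run_length must be >= 1")
    values = (
        np.asarray(series.weekly_iop[1:], float)
        if isinstance(series, IOPSeries)
        else np.asarray(series, float)
    )
    above = values > threshold
    for start in range(0, len(values) - run_length + 1):
        if above[start : start + run_length].all():
            return start + 1
    return None


def initial_injection_count(series: IOPSeries) -> int:
    """Number of injections in the initial consecutive weekly run.

    This is the "injections needed for IOP elevation" a study would report;
    sporadic later re-injections (fluctuation dips below the threshold) are
    excluded.
    """
    count = 0
    for week in series.injection_weeks:
        if week == count + 1:
            count += 1
        else:
            break
    return count


def _iop_level_trace(
    params: CohortParams,
    group: int,
    treatment: str,
    baseline: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, list[int]]:
    """Weekly measured IOP and injection weeks; rng=None gives the noise-free trace."""
    weeks = params.study_weeks
    measured = np.empty(weeks + 1)
    noise = (
        (lambda sd: rng.normal(0.0, sd)) if rng is not None else (lambda sd: 0.0)
    )
    measured[0] = max(baseline + noise(params.tonometry_noise_sd), 1.0)
    injections: list[int] = []
    plateau = params.plateau(group)
    threshold = params.reinjection_threshold(group)
    for w in range(1, weeks + 1):
        if treatment == "OHT":
            if measured[w - 1] < threshold:
                injections.append(w)
            response = sum(
                1.0 - math.exp(-(w - wi) / params.bead_response_tau)
                for wi in injections
            )
            level = baseline + min(
                response * params.injection_effect, max(plateau - baseline, 0.0)
            )
        else:
            rise = params.consensual_rise_mmhg if params.consensual_rise else 0.0
            level = baseline + rise * (1.0 - math.exp(-w / params.consensual_rise_tau))
        sd = params.tonometry_noise_sd + params.iop_fluctuation_cv * max(
            level - baseline, 0.0
        )
        measured[w] = max(level + noise(sd), 1.0)
    return measured, injections


def simulate_iop_series(
    params: CohortParams,
    group: int,
    treatment: str,
    seed: int | np.random.SeedSequence | None = None,
    primate_id: str = "sim",
    eye: str = "OD",
) -> IOPSeries:
    """Simulate one eye's weekly IOP series; reproducible given ``seed``."""
    if group not in (1, 2):
        raise ParameterError("group must be 1 or 2")
    if treatment not in ("OHT", "control"):
        raise ParameterError("treatment must be 'OHT' or 'control'")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    baseline = max(rng.normal(params.baseline_iop_mean, params.baseline_iop_sd), 4.0)
    measured, injections = _iop_level_trace(params, group, treatment, baseline, rng)
    series = IOPSeries(
        primate_id=primate_id,
        eye=eye,
        treatment=treatment,
        weekly_iop=measured,
        injection_weeks=tuple(injections),
        onset_week=None,
        baseline_iop=baseline,
    )
    onset = detect_onset(series, params.onset_threshold, params.onset_run_length)
    return replace(series, onset_week=onset)


def _monthly_means(params: CohortParams, weekly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean, max) per month 0..n; month 0 is the baseline reading."""
    wpm = params.weeks_per_month
    n_months = params.study_weeks // wpm
    means = np.empty(n_months + 1)
    maxes = np.empty(n_months + 1)
    means[0] = maxes[0] = weekly[0]
    for m in range(1, n_months + 1):
        block = weekly[(m - 1) * wpm + 1 : m * wpm + 1]
        means[m] = block.mean()
        maxes[m] = block.max()
    return means, maxes


def _expected_arm_iop(params: CohortParams, group: int, treatment: str) -> np.ndarray:
    """Noise-free expected monthly mean IOP for one arm (deterministic)."""
    weekly, _ = _iop_level_trace(
        params, group, treatment, params.baseline_iop_mean, rng=None
    )
    means, _ = _monthly_means(params, weekly)
    return means


def _structure_trajectory(
    params: CohortParams,
    treatment: str,
    monthly_mean_iop: np.ndarray,
    expected_iop: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Monthly MRW and LCD values, months 0..n."""
    n_months = len(monthly_mean_iop) - 1
    mrw = np.empty(n_months + 1)
    lcd = np.empty(n_months + 1)
    mrw[0] = rng.normal(params.baseline_mrw_mean, params.baseline_mrw_sd)
    lcd[0] = rng.normal(params.baseline_lcd_mean, params.baseline_lcd_sd)
    for m in range(n_months):  # interval m -> m+1
        oht_jump = treatment == "OHT" and m == 1
        shape_mrw = params.mrw_change_m1m2_mean if oht_jump else 0.0
        shape_lcd = params.lcd_change_m1m2_mean if oht_jump else 0.0
        k = max(min(m + 1 - params.iop_structure_lag, n_months), 0)
        dev = monthly_mean_iop[k] - expected_iop[k]
        sd_mrw = params.mrw_change_m1m2_sd if oht_jump else params.mrw_drift_noise_sd
        sd_lcd = params.lcd_change_m1m2_sd if oht_jump else params.lcd_drift_noise_sd
        mrw[m + 1] = mrw[m] + shape_mrw + params.iop_structure_slope_mrw * dev + (
            rng.normal(0.0, sd_mrw) if sd_mrw > 0 else 0.0
        )
        lcd[m + 1] = lcd[m] + shape_lcd + params.iop_structure_slope_lcd * dev + (
            rng.normal(0.0, sd_lcd) if sd_lcd > 0 else 0.0
        )
    return np.maximum(mrw, 1.0), lcd


def _cohort_eyes(params: CohortParams) -> Iterable[tuple[str, int, str, str]]:
    for i in range(params.n_group1):
        pid = f"G1-{i + 1:02d}"
        yield pid, 1, "OD", "OHT"
        yield pid, 1, "OS", "control"
    for i in range(params.n_group2):
        pid = f"G2-{i + 1:02d}"
        yield pid, 2, "OD", "OHT"
        yield pid, 2, "OS", "OHT"


def generate_cohort(
    params: CohortParams, return_series: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[tuple[str, str], IOPSeries]]:
    """Simulate the full two-group cohort as a long-format table.

    One row per (primate, eye, month); months 0 (baseline) through
    ``study_weeks // weeks_per_month``.  Bit-reproducible given
    ``params.seed``.
    """
    ss = np.random.SeedSequence(params.seed)
    eyes = list(_cohort_eyes(params))
    children = ss.spawn(len(eyes))
    expected = {
        (grp, trt): _expected_arm_iop(params, grp, trt)
        for grp, trt in {(g, t) for _, g, _, t in eyes}
    }

    rows = []
    series_map: dict[tuple[str, str], IOPSeries] = {}
    for (pid, group, eye, treatment), child in zip(eyes, children):
        rng = np.random.default_rng(child)
        baseline = max(
            rng.normal(params.baseline_iop_mean, params.baseline_iop_sd), 4.0
        )
        weekly, injections = _iop_level_trace(params, group, treatment, baseline, rng)
        series = IOPSeries(
            primate_id=pid,
            eye=eye,
            treatment=treatment,
            weekly_iop=weekly,
            injection_weeks=tuple(injections),
            onset_week=None,
            baseline_iop=baseline,
        )
        series = replace(
            series,
            onset_week=detect_onset(
                series, params.onset_threshold, params.onset_run_length
            ),
        )
        series_map[(pid, eye)] = series
        means, maxes = _monthly_means(params, weekly)
        mrw, lcd = _structure_trajectory(
            params, treatment, means, expected[(group, treatment)], rng
        )
        for m in range(len(means)):
            rows.append(
                (pid, eye, group, treatment, m, means[m], maxes[m], mrw[m], lcd[m])
            )

    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if return_series:
        return table, series_map
    return table
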