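"""Kaplan–Meier estimation, log-rank tests and median-OS dichotomization.

Overall survival (OS) runs from diagnosis to death from any cause, with
living patients censored at last follow-up; progression-free survival
(PFS) runs from diagnosis to progression or disease-related death. Curves
are product-limit estimates with exponential-Greenwood (log(−log))
confidence bands; groups are compared with the log-rank test. The
longer/shorter survival split used for the survival signature dichotomizes
the treated arm at its own Kaplan–Meier median OS.

Estimation is delegated to :mod:`lifelines`; this module fixes the
conventions (median definition, CI scale, handling of subjects censored
before the median) and adapts the inputs/outputs to the pipeline's tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from cpgrank.core_io import SampleSheet, ValidationError


@dataclass
class SurvivalCurve:
    """Product-limit estimate of a survival function.

    ``table`` has one row per distinct event time (ascending): at_risk,
    events, censored, survival, ci_lower, ci_upper. ``median`` is the
    smallest time with S(t) ≤ 0.5 (NaN when the curve never drops that
    far); ``median_ci`` comes from where the confidence bands cross 0.5.
    """

    table: pd.DataFrame
    median: float
    median_ci: tuple[float, float]
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        past = self.table.loc[self.table.index <= t, "survival"]
        return float(past.iloc[-1]) if len(past) else 1.0


def _validate_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValidationError("need at least one observation")
    if times.shape != events.shape:
        raise ValidationError("times and events must have the same length")
    if np.isnan(times).any() or (times < 0).any():
        raise ValidationError("survival times must be non-negative and non-missing")
    if not np.isin(events[~np.isnan(events)], [0, 1]).all() or np.isnan(events).any():
        raise ValidationError("event indicators must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with Greenwood log(−log) bands."""
    times, events = _validate_times(times, events)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)

    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    table = pd.DataFrame(
        {
            "at_risk": ev["at_risk"],
            "events": ev["observed"],
            "censored": ev["censored"],
            "survival": surv,
            "ci_lower": ci.iloc[:, 0],
            "ci_upper": ci.iloc[:, 1],
        }
    )
    table.index.name = "time"

    median = float(kmf.median_survival_time_)
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    return SurvivalCurve(
        table=table,
        median=median if math.isfinite(median) else float("nan"),
        median_ci=(lo if math.isfinite(lo) else float("nan"),
                   hi if math.isfinite(hi) else float("nan")),
        n=len(times),
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    Tied event times are handled exactly through the summed hypergeometric
    moments of the pooled risk sets.
    """
    times, events = _validate_times(times, events)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, got {len(levels)}")
    a = group == levels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    return float(res.test_statistic), float(res.p_value)


def define_os_pfs(sheet: SampleSheet) -> pd.DataFrame:
    """Per-subject (time, event) pairs for OS and PFS; controls excluded.

    Uses each subject's diagnosis row. Raises listing the offending
    subjects when survival columns are missing for a non-control patient.
    """
    df = sheet.table
    df = df[(df["timepoint"] == "diagnosis") & (df["disease"] != "control")]
    missing = df.loc[
        df[["os_months", "os_event", "pfs_months", "pfs_event"]].isna().any(axis=1),
        "subject_id",
    ]
    if len(missing):
        raise ValidationError(f"missing survival data for subjects: {list(missing)}")
    out = df[["subject_id", "treatment", "os_months", "os_event", "pfs_months", "pfs_event"]]
    return out.reset_index(drop=True)


def dichotomize_by_median_os(surv: pd.DataFrame) -> pd.Series:
    """Split subjects at the arm's Kaplan–Meier median OS.

    ``shorter``: died at or before the median; ``longer``: observed (event
    or censoring) beyond the median; ``indeterminate``: censored at or
    before the median — their true survival relative to the median is
    unknown, so they are excluded from two-group comparisons.

    ``surv`` is a ``define_os_pfs``-style frame (already restricted to the
    treatment arm of interest). Raises when the KM median is undefined.
    """
    if len(surv) < 2:
        raise ValidationError("need >=2 subjects to dichotomize")
    curve = km_estimate(surv["os_months"], surv["os_event"])
    m = curve.median
    if not math.isfinite(m):
        raise ValidationError(
            "KM median OS undefined (curve never reaches 0.5); "
            "use a fixed-time split instead"
        )
    labels = []
    for _, row in surv.iterrows():
        t, e = row["os_months"], row["os_event"]
        if t > m:
            labels.append("longer")
        elif e == 1:
            labels.append("shorter")
        else:
            labels.append("indeterminate")
    return pd.Series(labels, index=surv["subject_id"].to_numpy(), name="os_group")
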