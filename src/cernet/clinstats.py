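"""Survival screening and cohort statistics.

Median-split grouping of patients by expression of a candidate transcript,
Kaplan–Meier product-limit estimation, the two-group log-rank test, cohort
summary tables (count and percent per clinical category), 2^-ddCt relative
quantification for qRT-PCR, and one-way ANOVA with Dunnett's many-to-one
comparison against a control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


def median_split(values: pd.Series) -> pd.Series:
    """Label each subject ``high`` (value > median) or ``low`` (<= median).

    Raises on a constant vector (no split possible) or fewer than 2
    subjects.
    """
    if len(values) < 2:
        raise ValueError("median split needs >=2 subjects")
    med = float(values.median())
    if float(values.min()) == float(values.max()):
        raise ValueError("constant expression vector: no median split possible")
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index, name="group")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("median split produced an empty group")
    return labels


@dataclass
class KMCurve:
    """Product-limit survival estimate: S starts at 1 and never increases."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier estimate from a frame with ``time`` and ``event`` columns.

    Censored subjects leave the risk set without creating a step.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(bool)
    if (time < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    times = tbl.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(float)
    at_risk = tbl["at_risk"].to_numpy(float)
    keep = times > 0  # drop the t=0 anchor row if present
    if not keep.all():
        times, surv, at_risk = times[keep], surv[keep], at_risk[keep]
    return KMCurve(event_times=times, survival=surv, at_risk=at_risk)


def logrank_test(records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p-value.

    ``records`` needs columns ``time``, ``event``, ``group`` with exactly
    two group labels and at least one observed event overall.
    """
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups}")
    if not records["event"].astype(bool).any():
        raise ValueError("log-rank test needs >=1 observed event")
    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    res = _ll_logrank(
        a["time"].to_numpy(float), b["time"].to_numpy(float),
        event_observed_A=a["event"].to_numpy(bool),
        event_observed_B=b["event"].to_numpy(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matching hand-tabulated percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(clinical: pd.DataFrame, total: int | None = None) -> dict[str, list[tuple[str, int, float]]]:
    """Per-variable category counts and percentages of the cohort.

    ``clinical`` holds one row per subject and one categorical column per
    variable.  Percent = 100*count/total rounded half-away-from-zero to
    one decimal; ``total`` defaults to the number of rows.
    """
    n = total if total is not None else len(clinical)
    if n <= 0:
        raise ValueError("cohort size must be positive")
    out: dict[str, list[tuple[str, int, float]]] = {}
    for var in clinical.columns:
        counts = clinical[var].value_counts()
        rows = []
        for cat in sorted(counts.index.astype(str)):
            c = int(counts[cat])
            if c < 0:
                raise ValueError("negative count")
            rows.append((cat, c, round_half_up(100.0 * c / n, 1)))
        out[var] = rows
    return out


def category_percent(count: int, total: int) -> float:
    """Percent of cohort, rounded half-away-from-zero to one decimal."""
    if total <= 0:
        raise ValueError("cohort size must be positive")
    if count < 0:
        raise ValueError("negative count")
    return round_half_up(100.0 * count / total, 1)


def cohort_table_frame(summary: dict[str, list[tuple[str, int, float]]]) -> pd.DataFrame:
    rows = [
        {"variable": var, "category": cat, "count": c, "percent": pct}
        for var, entries in summary.items()
        for cat, c, pct in entries
    ]
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) within each sample;
    ddCt = dCt(sample) - dCt(calibrator); fold = 2^-ddCt.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** -ddct)


def anova_dunnett(
    groups: dict[str, np.ndarray], control: str, seed: int | None = None
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F-test plus Dunnett many-to-one comparisons.

    Returns (F, anova_p, frame) where the frame has one row per
    non-control group with its Dunnett-adjusted two-sided p-value against
    the control.  The adjustment integrates the multivariate-t null of the
    maximal |t| statistic under the pooled error variance; ``seed`` fixes
    the stochastic quadrature.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} absent")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    if len(groups) < 2:
        raise ValueError("need the control plus >=1 comparison group")
    names = sorted(k for k in groups if k != control)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    ctrl = np.asarray(groups[control], dtype=float)
    f_stat, anova_p = stats.f_oneway(ctrl, *arrays)
    rng = np.random.default_rng(seed)
    res = stats.dunnett(*arrays, control=ctrl, rng=rng)
    frame = pd.DataFrame(
        {"group": names, "statistic": res.statistic, "p_adjusted": res.pvalue}
    )
    return float(f_stat), float(anova_p), frame
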