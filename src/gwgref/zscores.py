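"""Weight-gain-for-gestational-age Z-scores and adequacy measures.

A pregnancy's total gestational weight gain (GWG) is the last antenatal
weight at or before delivery minus the baseline weight.  Standardized
against the cohort- and BMI-group-specific reference chart for the
gestational week of that last measurement, it becomes a
weight-gain-for-gestational-age Z-score:

    z = (y - mu_log(t)) / sd_log,    y = ln(total_gwg + 5)

computed on the transformed scale by default (the scale on which the
reference model is normal); a kg-scale variant is available for external
standards published as kg means/SDs.  Z-scores are grouped at the
standard-normal quartile cut-offs +/-0.6745 (G1 <= 25th percentile,
G2 26-50th, G3 51-75th, G4 > 75th; G3 is the reference group downstream).

The module also implements the guideline adequacy ratio: observed total
gain divided by the gain a guideline recommends for the same gestation,
where recommended gain = first-trimester allowance + weekly rate x
(weeks - 13) with BMI-specific constants (2 kg then 0.51 kg/wk for
underweight; 2 kg, 0.42 for normal; 0.5 kg, 0.28 for overweight;
0.5 kg, 0.22 for obese), and a plugin seam for external
weight-gain-for-gestational-age standards supplied as (mean, SD) by week.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .reference import transform_gwg

__all__ = [
    "Z_Q25",
    "Z_Q75",
    "total_gwg",
    "compute_total_gwg",
    "gwg_zscore",
    "zscore_group",
    "iom_recommended",
    "iom_adequacy_ratio",
    "AdequacyResult",
    "ExternalStandard",
    "TableStandard",
    "ChartStandard",
    "external_standard_zscore",
    "trimester_gwg",
]

#: full-precision standard-normal quartile cut-offs (displayed as -0.67 / 0.67)
Z_Q25 = float(stats.norm.ppf(0.25))
Z_Q75 = float(stats.norm.ppf(0.75))

GROUP_LABELS = ("G1", "G2", "G3", "G4")

#: first-trimester recommended gain (kg) by BMI group
IOM_T1_GAIN = {"underweight": 2.0, "normal": 2.0, "overweight": 0.5, "obese": 0.5}
#: 2nd/3rd-trimester recommended weekly rate (kg/week) by BMI group
IOM_WEEKLY_RATE = {"underweight": 0.51, "normal": 0.42, "overweight": 0.28, "obese": 0.22}
#: recommended total-gain range (kg) at term by BMI group
IOM_TOTAL_RANGE = {
    "underweight": (12.5, 18.0),
    "normal": (11.5, 16.0),
    "overweight": (7.0, 11.5),
    "obese": (5.0, 9.0),
}


def total_gwg(visits: pd.DataFrame, baseline_weight_kg: float, delivery_ga_weeks: float):
    """Total gain for one pregnancy: latest valid visit at/before delivery.

    Returns ``(total_gwg_kg, ga_last_weeks)``; the visit's gestational age
    is the week at which the gain is standardized.
    """
    v = visits
    if "valid" in v.columns:
        v = v[v["valid"]]
    v = v[v["ga_weeks"] <= delivery_ga_weeks]
    if v.empty:
        raise ValueError("no valid weight measurement at or before delivery")
    last = v.loc[v["ga_weeks"].idxmax()]
    return float(last["weight_kg"] - baseline_weight_kg), float(last["ga_weeks"])


def compute_total_gwg(
    visits: pd.DataFrame, baselines: pd.DataFrame, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized :func:`total_gwg` over a cohort table.

    Returns one row per participant having at least one valid visit at or
    before delivery: ``participant_id, cohort, bmi_group, total_gwg_kg,
    ga_last_weeks``.
    """
    v = visits
    if "valid" in v.columns:
        v = v[v["valid"]]
    merged = v.merge(
        outcomes[["participant_id", "delivery_ga_weeks"]], on="participant_id"
    )
    merged = merged[merged["ga_weeks"] <= merged["delivery_ga_weeks"]]
    idx = merged.groupby("participant_id")["ga_weeks"].idxmax()
    last = merged.loc[idx]
    out = last.merge(
        baselines[["participant_id", "baseline_weight_kg", "bmi_group"]],
        on="participant_id",
    )
    out["total_gwg_kg"] = out["weight_kg"] - out["baseline_weight_kg"]
    out = out.rename(columns={"ga_weeks": "ga_last_weeks"})
    return out[["participant_id", "cohort", "bmi_group", "total_gwg_kg", "ga_last_weeks"]]


def _chart_lookup(chart: pd.DataFrame, cohort, bmi_group, week: int) -> pd.Series:
    row = chart[
        (chart["cohort"] == cohort)
        & (chart["bmi_group"] == bmi_group)
        & (chart["ga_week"] == week)
    ]
    if row.empty:
        raise ValueError(
            f"gestational week {week} for ({cohort!r}, {bmi_group!r}) is "
            "outside the chart's support"
        )
    return row.iloc[0]


def gwg_zscore(
    total_gwg_kg: float,
    ga_last_weeks: float,
    chart: pd.DataFrame,
    cohort,
    bmi_group,
    scale: str = "log",
    interpolate: bool = False,
) -> float:
    """Standardize a total gain against the reference chart.

    ``scale="log"`` (default) standardizes ``ln(gwg + 5)`` against the
    chart's transformed-scale mean/SD; ``scale="kg"`` standardizes the raw
    gain against the back-transformed median and a kg-scale SD derived
    from the p50-p75 spread.  Chart rows are published per integer week;
    by default the nearest week is used (``interpolate=True`` blends the
    two bracketing weeks linearly).
    """
    if scale not in ("log", "kg"):
        raise ValueError(f"unknown scale {scale!r}")

    def params_at(week: int):
        row = _chart_lookup(chart, cohort, bmi_group, week)
        if scale == "log":
            return row["mu_log"], row["sd_log"]
        med = row["p50"]
        sd_kg = (row["p75"] - row["p50"]) / Z_Q75
        return med, sd_kg

    if interpolate:
        lo = int(np.floor(ga_last_weeks))
        hi = int(np.ceil(ga_last_weeks))
        w = ga_last_weeks - lo
        mu_lo, sd_lo = params_at(lo)
        mu_hi, sd_hi = params_at(hi) if hi != lo else (mu_lo, sd_lo)
        mu, sd = (1 - w) * mu_lo + w * mu_hi, (1 - w) * sd_lo + w * sd_hi
    else:
        mu, sd = params_at(int(round(ga_last_weeks)))

    value = transform_gwg(total_gwg_kg) if scale == "log" else total_gwg_kg
    return float((value - mu) / sd)


def zscore_group(z):
    """Standard-normal quartile group of a Z-score.

    G1: z <= q25; G2: q25 < z <= 0; G3: 0 < z <= q75; G4: z > q75, with the
    cut-offs at full precision (+/-0.67449, displayed rounded to 0.67).
    Accepts scalars or arrays; every finite z maps to exactly one group.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("Z-scores must be finite")
    out = np.select(
        [z <= Z_Q25, z <= 0.0, z <= Z_Q75],
        ["G1", "G2", "G3"],
        default="G4",
    )
    return out.item() if out.ndim == 0 else out


def zscore_percentile(z):
    """Percentile position Phi(z) * 100 of a Z-score."""
    return stats.norm.cdf(z) * 100.0


def iom_recommended(bmi_group: str, ga_final_weeks: float) -> float:
    """Guideline-recommended total gain (kg) at a final gestational age.

    First-trimester allowance plus the BMI-specific weekly rate applied to
    the weeks beyond 13.  Pregnancies ending before 13 weeks are outside
    the formula's support.
    """
    if ga_final_weeks < 13:
        raise ValueError("recommended-gain formula applies from 13 weeks onward")
    if bmi_group not in IOM_T1_GAIN:
        raise KeyError(f"unknown BMI group {bmi_group!r}")
    return IOM_T1_GAIN[bmi_group] + IOM_WEEKLY_RATE[bmi_group] * (ga_final_weeks - 13)


@dataclass(frozen=True)
class AdequacyResult:
    observed_gwg_kg: float
    recommended_gwg_kg: float
    ratio: float                      # (observed / recommended) * 100, percent
    iom_category: str | None = None   # below / adequate / above the total range


def iom_adequacy_ratio(
    observed_kg: float, recommended_kg: float, bmi_group: str | None = None
) -> AdequacyResult:
    """Adequacy ratio (observed/recommended x 100) and total-range category.

    The category compares the observed *total* gain with the guideline
    total-gain range for the BMI group (supplied separately from the
    ratio's gestation-adjusted denominator); it is omitted when the BMI
    group is not given.
    """
    if recommended_kg <= 0:
        raise ValueError("recommended gain must be positive")
    ratio = observed_kg / recommended_kg * 100.0
    category = None
    if bmi_group is not None:
        lo, hi = IOM_TOTAL_RANGE[bmi_group]
        category = "below" if observed_kg < lo else ("above" if observed_kg > hi else "adequate")
    return AdequacyResult(float(observed_kg), float(recommended_kg), float(ratio), category)


class ExternalStandard:
    """Interface for an external weight-gain-for-gestational-age standard.

    A standard declares a gestational-age support and returns a (mean, SD)
    pair — on the kg scale unless it states otherwise — for any week in
    support.  Published coefficient sets (e.g. international GWG standards
    for normal-BMI women) are wrapped by the caller; none are embedded here.
    """

    support: tuple[float, float]
    scale: str = "kg"

    def mean_sd(self, ga_weeks: float) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError


class TableStandard(ExternalStandard):
    """External standard backed by a per-week (mean, sd) table."""

    def __init__(self, table: pd.DataFrame, scale: str = "kg"):
        if not {"ga_week", "mean", "sd"} <= set(table.columns):
            raise ValueError("table needs columns ga_week, mean, sd")
        self._table = table.set_index("ga_week")
        self.support = (float(table["ga_week"].min()), float(table["ga_week"].max()))
        self.scale = scale

    def mean_sd(self, ga_weeks: float) -> tuple[float, float]:
        week = int(round(ga_weeks))
        if week not in self._table.index:
            raise ValueError(f"week {week} outside standard support {self.support}")
        row = self._table.loc[week]
        return float(row["mean"]), float(row["sd"])


class ChartStandard(ExternalStandard):
    """Adapter presenting this package's own chart as an external standard."""

    def __init__(self, chart: pd.DataFrame, cohort, bmi_group):
        self._chart, self._cohort, self._bmi = chart, cohort, bmi_group
        sub = chart[(chart["cohort"] == cohort) & (chart["bmi_group"] == bmi_group)]
        self.support = (float(sub["ga_week"].min()), float(sub["ga_week"].max()))
        self.scale = "log"

    def mean_sd(self, ga_weeks: float) -> tuple[float, float]:
        row = _chart_lookup(self._chart, self._cohort, self._bmi, int(round(ga_weeks)))
        return float(row["mu_log"]), float(row["sd_log"])


def external_standard_zscore(
    total_gwg_kg: float, ga_weeks: float, standard: ExternalStandard
) -> float:
    """Z-score of a total gain against a supplied external standard."""
    lo, hi = standard.support
    if not (lo <= ga_weeks <= hi):
        raise ValueError(
            f"gestational age {ga_weeks} outside standard support [{lo}, {hi}]"
        )
    mean, sd = standard.mean_sd(ga_weeks)
    value = transform_gwg(total_gwg_kg) if standard.scale == "log" else total_gwg_kg
    return float((value - mean) / sd)


def trimester_gwg(visits: pd.DataFrame, baseline_weight_kg: float):
    """Second- and third-trimester gains for one pregnancy.

    Second trimester: last valid weight in [14, 28) weeks minus baseline;
    third: last valid weight at >= 28 weeks minus baseline.  ``None`` when
    no qualifying visit exists.  Trimester windows follow standard
    obstetric convention.
    """
    v = visits
    if "valid" in v.columns:
        v = v[v["valid"]]

    def last_in(mask):
        sub = v[mask]
        if sub.empty:
            return None
        return float(sub.loc[sub["ga_weeks"].idxmax(), "weight_kg"] - baseline_weight_kg)

    t2 = last_in((v["ga_weeks"] >= 14) & (v["ga_weeks"] < 28))
    t3 = last_in(v["ga_weeks"] >= 28)
    return t2, t3
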