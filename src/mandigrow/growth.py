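"""Longitudinal growth summaries and the orientation-effect statistics.

For a parameter series v_1..v_T (T monthly timepoints):

* total change            D = v_T - v_1
* normalized total change N = D / v_1          (scale-free)
* monthly change          d_t = v_t - v_{t-1}  (t = 2..T)
* percent of change       p_t = 100 (v_t - v_1) / D
* half-growth month       smallest t with p_t >= 50 (no interpolation)

Orientation effect: each subject contributes one mean normalized total
change per orientation group (AP, SI, ML, AI); a one-way repeated-
measures ANOVA tests the group effect, followed (when significant at
alpha) by all six paired t-tests against the Bonferroni threshold
alpha/6 (0.05/6 = 0.008333..., stored at full precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaReport",
    "GrowthSummary",
    "ParameterSeries",
    "dose_budget",
    "group_summary",
    "growth_summary",
    "rm_anova_orientation",
    "subject_group_means",
    "summarize_study",
]


@dataclass
class ParameterSeries:
    """One measured parameter across T1..T_T for one subject."""

    subject: str
    parameter: str
    group: str
    values: np.ndarray
    units: str = "cm"
    timepoints: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints is None:
            self.timepoints = np.arange(1, len(self.values) + 1)
        else:
            self.timepoints = np.asarray(self.timepoints, dtype=int)
        if len(self.values) != len(self.timepoints):
            raise ValueError("values and timepoints length mismatch")
        if len(self.values) < 2:
            raise ValueError("a series needs at least 2 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.parameter}: missing timepoint value")
        expected = np.arange(self.timepoints[0], self.timepoints[0] + len(self.values))
        if not np.array_equal(self.timepoints, expected):
            raise ValueError(f"{self.parameter}: non-contiguous timepoints")


@dataclass
class GrowthSummary:
    initial: float
    final: float
    total_change: float
    normalized_total_change: float
    monthly_changes: np.ndarray  # length T-1, t = 2..T
    percent_of_change: np.ndarray  # length T, p_1 = 0, p_T = 100
    half_growth_month: int | None
    degenerate: bool  # True when total change is 0 (percent series undefined)


def growth_summary(series: ParameterSeries) -> GrowthSummary:
    """Descriptive growth quantities of one series (exact arithmetic)."""
    v = series.values
    t = series.timepoints
    initial, final = float(v[0]), float(v[-1])
    if initial <= 0:
        raise ValueError(f"{series.parameter}: initial value must be positive")
    delta = final - initial
    monthly = np.diff(v)
    if delta == 0:
        percent = np.full(len(v), np.nan)
        return GrowthSummary(initial, final, 0.0, 0.0, monthly, percent, None, True)
    percent = 100.0 * (v - initial) / delta
    half_idx = np.flatnonzero(percent >= 50.0)
    half_month = int(t[half_idx[0]]) if len(half_idx) else None
    return GrowthSummary(
        initial, final, delta, delta / initial, monthly, percent, half_month, False
    )


def summarize_study(
    measurements: pd.DataFrame, side: str = "L"
) -> pd.DataFrame:
    """Growth summaries for every (subject, parameter) in a measurement table.

    ``measurements`` is the long-format output of ``measure_all`` stacked
    over subjects and timepoints. Unilateral parameters are taken from
    ``side`` ("L", "R" or "mean"); bilateral ones from their single "B"
    row. Returns one row per subject x parameter with the scalar summary
    fields (monthly/percent series are kept in ``summarize_series``-style
    long tables by the pipeline).
    """
    rows = []
    picked = measurements[measurements.side.isin([side, "B"])]
    for (subj, param), sub in picked.groupby(["subject", "parameter"], sort=True):
        sub = sub.sort_values("timepoint")
        series = ParameterSeries(
            subj, param, sub.group.iloc[0], sub.value.to_numpy(),
            units=sub.units.iloc[0], timepoints=sub.timepoint.to_numpy(),
        )
        g = growth_summary(series)
        rows.append(
            {
                "subject": subj, "parameter": param, "group": series.group,
                "initial": g.initial, "final": g.final,
                "total_change": g.total_change,
                "normalized_total_change": g.normalized_total_change,
                "half_growth_month": g.half_growth_month,
                "degenerate": g.degenerate,
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    normalized: pd.Series | dict,
    grouping: dict,
) -> pd.DataFrame:
    """Unweighted mean (SD) of normalized total changes over group members.

    ``normalized`` maps parameter name -> normalized total change (the
    per-parameter value, typically already averaged over subjects);
    ``grouping`` maps group name -> list of member parameter names.
    SD is the sample standard deviation over member parameters (0 for a
    single-member group).
    """
    if isinstance(normalized, dict):
        normalized = pd.Series(normalized)
    rows = []
    for group, members in grouping.items():
        if not members:
            raise ValueError(f"group {group!r} has no member parameters")
        missing = [m for m in members if m not in normalized.index]
        if missing:
            raise KeyError(f"group {group!r}: missing parameters {missing}")
        vals = normalized[members].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {"group": group, "n_members": len(vals),
             "mean": float(np.mean(vals)), "sd": sd}
        )
    return pd.DataFrame(rows)


def subject_group_means(summaries: pd.DataFrame, groups=("AP", "SI", "AI", "ML")) -> pd.DataFrame:
    """Per-subject mean normalized total change of each orientation group.

    Returns a wide frame (index subject, one column per group) — the
    repeated-measures layout of the orientation ANOVA.
    """
    sub = summaries[summaries.group.isin(groups)]
    wide = sub.pivot_table(
        index="subject", columns="group", values="normalized_total_change",
        aggfunc="mean",
    )[list(groups)]
    if wide.isna().any().any():
        raise ValueError("missing orientation-group cells for some subject")
    return wide


# ----- repeated-measures ANOVA ----------------------------------------------


@dataclass
class AnovaReport:
    effect: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    gg_epsilon: float
    p_value_gg: float
    alpha: float
    bonferroni_threshold: float
    effect_significant: bool
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rm_anova_f(y: np.ndarray) -> tuple[float, int, int, float]:
    """One-way within-subject ANOVA from the sums-of-squares decomposition."""
    n, k = y.shape
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    # guard exact degeneracies against float roundoff in the decomposition
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_err <= tol:
        if ss_cond <= tol:
            return 0.0, df1, df2, 1.0
        return np.inf, df1, df2, 0.0
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False, ddof=1)
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * np.sum(s_dc**2)
    if denom <= 0:
        return 1.0
    eps = np.trace(s_dc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_orientation(
    group_values: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    effect: str = "orientation",
) -> AnovaReport:
    """Orientation effect on normalized total changes (one-way rm-ANOVA).

    ``group_values`` is subjects x groups (a wide DataFrame from
    ``subject_group_means`` or a plain array). When the effect is
    significant at ``alpha``, all pairwise paired t-tests are run and
    flagged against the Bonferroni threshold alpha / n_pairs.
    """
    if isinstance(group_values, pd.DataFrame):
        names = list(group_values.columns)
        y = group_values.to_numpy(dtype=float)
    else:
        y = np.asarray(group_values, dtype=float)
        names = [f"g{i+1}" for i in range(y.shape[1])]
    if y.ndim != 2:
        raise ValueError("group_values must be 2-D (subjects x groups)")
    n, k = y.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    if not np.isfinite(y).all():
        raise ValueError("missing cells are not allowed")

    f, df1, df2, p = _rm_anova_f(y)
    eps = _gg_epsilon(y)
    p_gg = float(sps.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
    n_pairs = k * (k - 1) // 2
    threshold = alpha / n_pairs
    significant = p < alpha

    rows = []
    if significant:
        for i, j in combinations(range(k), 2):
            t_stat, p_t = sps.ttest_rel(y[:, i], y[:, j])
            rows.append(
                {
                    "pair": f"{names[i]}-{names[j]}",
                    "t": float(t_stat),
                    "p": float(p_t),
                    "threshold": threshold,
                    "significant": bool(p_t < threshold),
                }
            )
    pairwise = pd.DataFrame(
        rows, columns=["pair", "t", "p", "threshold", "significant"]
    )
    return AnovaReport(
        effect=effect, f_statistic=f, df_num=df1, df_den=df2, p_value=p,
        gg_epsilon=eps, p_value_gg=p_gg, alpha=alpha,
        bonferroni_threshold=threshold, effect_significant=significant,
        pairwise=pairwise,
    )


# ----- radiation dose bookkeeping -------------------------------------------


def dose_budget(per_scan_dose_usv: float, n_scans: int) -> float:
    """Cumulative dose over a scan protocol, in mSv (input per-scan in uSv)."""
    if per_scan_dose_usv < 0 or n_scans < 0:
        raise ValueError("dose and scan count must be non-negative")
    return per_scan_dose_usv * n_scans / 1000.0
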