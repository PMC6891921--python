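"""Group statistics and normalization for morphometry/permeability tables.

The measurement tables are long-format DataFrames with columns
``experiment_id, device_id, condition, metric_name, value``.  The device
is the replication unit: field-of-view values are averaged per device
before any test.  Normalization to control is per experiment (each value
divided by its own experiment's control mean), cytokine arrays are
min-max scaled per cytokine to [0, 1], and group comparisons use one-way
ANOVA with Tukey HSD post-hoc tests, or two-sample (Welch) / paired
t-tests where the design asks for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TABLE_COLUMNS",
    "normalize_to_control",
    "minmax_scale",
    "compare_groups",
    "GroupComparison",
    "significance_stars",
    "device_means",
    "report",
]

TABLE_COLUMNS = ["experiment_id", "device_id", "condition", "metric_name", "value"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")


def normalize_to_control(
    table: pd.DataFrame, metric: str, control_label: str
) -> pd.DataFrame:
    """Divide each value by the mean control value of its own experiment.

    Only rows of ``metric`` are rescaled; the control group's normalized
    mean is exactly 1 within every experiment.  Raises if any experiment
    lacks control rows for the metric.
    """
    _check_table(table)
    out = table.copy()
    sel = out["metric_name"] == metric
    for exp_id, grp in out[sel].groupby("experiment_id"):
        ctrl = grp.loc[grp["condition"] == control_label, "value"]
        if ctrl.empty:
            raise ValueError(
                f"experiment {exp_id!r} has no {control_label!r} rows for metric {metric!r}"
            )
        out.loc[sel & (out["experiment_id"] == exp_id), "value"] /= ctrl.mean()
    return out


def minmax_scale(matrix: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame | np.ndarray, list]:
    """Scale each row (cytokine) to [0, 1] across conditions.

    ``(x - min) / (max - min)`` per row; a constant row cannot be scaled
    and is emitted as mid-level 0.5 and returned in the flag list.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D cytokine matrix (rows = cytokines)")
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    span_safe = np.where(span == 0, 1.0, span)
    scaled = (arr - lo) / span_safe
    scaled[flat, :] = 0.5
    flagged = (
        [matrix.index[i] for i in np.nonzero(flat)[0]] if is_df else list(np.nonzero(flat)[0])
    )
    if is_df:
        return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), flagged
    return scaled, flagged


def significance_stars(p: float) -> str:
    for thresh, stars in [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")]:
        if p < thresh:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    stars: str
    groups: list[str]
    tukey: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def device_means(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Average field-of-view values per device (the replication unit)."""
    _check_table(table)
    sub = table[table["metric_name"] == metric]
    return (
        sub.groupby(["experiment_id", "device_id", "condition"], as_index=False)["value"]
        .mean()
    )


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    design: str = "anova",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare conditions for one metric.

    ``design`` is ``"anova"`` (one-way ANOVA + Tukey HSD pairwise
    comparisons), ``"ttest"`` (Welch two-sample) or ``"paired"``
    (paired t-test on device-matched values).  Values are aggregated to
    device means first.
    """
    per_device = device_means(table, metric)
    groups = {c: g["value"].to_numpy() for c, g in per_device.groupby("condition")}
    labels = sorted(groups)
    bad = [c for c in labels if len(groups[c]) < 2]
    if len(labels) < 2 or bad:
        raise ValueError(
            f"need >= 2 groups with >= 2 device values each; degenerate groups: {bad or labels}"
        )

    if design == "anova":
        F, p = sps.f_oneway(*(groups[c] for c in labels))
        tukey_df = None
        if p < alpha:
            values = np.concatenate([groups[c] for c in labels])
            conds = np.concatenate([[c] * len(groups[c]) for c in labels])
            res = pairwise_tukeyhsd(values, conds, alpha=alpha)
            tukey_df = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        return GroupComparison(
            test="one-way ANOVA",
            statistic=float(F),
            p_value=float(p),
            stars=significance_stars(float(p)),
            groups=labels,
            tukey=tukey_df,
        )
    if design in ("ttest", "paired"):
        if len(labels) != 2:
            raise ValueError(f"{design} requires exactly 2 groups, got {labels}")
        a, b = groups[labels[0]], groups[labels[1]]
        if design == "paired":
            if len(a) != len(b):
                raise ValueError("paired design requires equal group sizes")
            t, p = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            name = "Welch t-test"
        return GroupComparison(
            test=name,
            statistic=float(t),
            p_value=float(p),
            stars=significance_stars(float(p)),
            groups=labels,
        )
    raise ValueError(f"unknown design {design!r}")


def report(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-condition mean ± s.e.m. summary over device means.

    Returns a tidy DataFrame with columns ``metric_name, condition, n,
    mean, sem, flags``; a single-device group has no s.e.m. and is
    flagged.
    """
    _check_table(table)
    if metrics is None:
        metrics = sorted(table["metric_name"].unique())
    rows = []
    for metric in metrics:
        per_device = device_means(table, metric)
        for cond, grp in per_device.groupby("condition"):
            vals = grp["value"].to_numpy()
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "metric_name": metric,
                    "condition": cond,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sem": sem,
                    "flags": "" if len(vals) > 1 else "single_value",
                }
            )
    return pd.DataFrame(rows)
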