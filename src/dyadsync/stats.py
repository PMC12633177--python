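"""Group comparisons and correlations for IBS and language metrics.

The statistical stage mirrors a three-group between-dyads design: per
channel pair (or language metric), a one-way ANOVA across groups followed
by two-tailed post-hoc t-tests (Welch by default, robust to the unequal
group sizes typical of clinical cohorts), with Benjamini-Hochberg FDR
correction across the family of channel pairs within each task.  Kendall
tau-b correlations then relate the IBS of flagged channels to behavioral
and symptom scores within the clinical group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_oneway",
    "posthoc_ttests",
    "bh_fdr",
    "kendall",
    "CorrelationResult",
    "run_full_analysis",
]


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 usable values")
        out[name] = arr
    return out


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    groups = _validate_groups(groups)
    res = sps.f_oneway(*groups.values())
    return float(res.statistic), float(res.pvalue)


def posthoc_ttests(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests for the requested group pairs.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled version).  Returns a tidy frame with columns
    (group_1, group_2, t, p, n_1, n_2).
    """
    groups = _validate_groups(groups)
    names = sorted(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise KeyError(f"unknown group in pair ({a!r}, {b!r})")
        res = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        rows.append(
            {
                "group_1": a,
                "group_2": b,
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "n_1": groups[a].size,
                "n_2": groups[b].size,
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(q, reject)`` where ``q`` are the monotone adjusted p-values
    (cumulative minimum from the largest rank downward) and ``reject`` the
    step-up decision at level ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def kendall(x, y) -> "CorrelationResult":
    """Kendall tau-b (tie-corrected) correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for an all-tied variable")
    res = sps.kendalltau(x, y)
    return CorrelationResult(tau=float(res.statistic), p=float(res.pvalue), n=x.size)


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# full statistical stage
# ---------------------------------------------------------------------------

@dataclass
class StatsConfig:
    alpha: float = 0.05
    equal_var: bool = False
    #: FDR family: "anova" corrects the per-channel ANOVA p-values,
    #: "posthoc" the pairwise p-values, "both" applies each in turn
    fdr_on: str = "anova"
    #: group whose dyads enter the correlation stage (the clinical group)
    correlation_group: str = "A"


def group_comparison_table(
    values: pd.DataFrame,
    value_col: str,
    unit_col: str,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """ANOVA + post-hoc + BH-FDR for every unit (channel pair or metric).

    ``values`` is tidy with columns (unit_col, "group", value_col).  Returns
    one row per unit with F, p, q, significance flag and the post-hoc
    two-tailed t/p per group pair (FDR-corrected as configured).
    """
    config = config or StatsConfig()
    rows = []
    posthoc_frames = []
    for unit, sub in values.groupby(unit_col, sort=True):
        groups = {
            g: gsub[value_col].to_numpy() for g, gsub in sub.groupby("group")
        }
        try:
            f, p = anova_oneway(groups)
        except ValueError:
            continue
        ph = posthoc_ttests(groups, equal_var=config.equal_var)
        ph[unit_col] = unit
        posthoc_frames.append(ph)
        rows.append({unit_col: unit, "F": f, "p": p})
    if not rows:
        raise ValueError("no unit had enough data for a group comparison")
    table = pd.DataFrame(rows)
    if config.fdr_on in ("anova", "both"):
        table["q"], table["significant"] = bh_fdr(table["p"], config.alpha)
    else:
        table["q"] = table["p"]
        table["significant"] = table["p"] < config.alpha
    posthoc = pd.concat(posthoc_frames, ignore_index=True)
    if config.fdr_on in ("posthoc", "both"):
        posthoc["q"], posthoc["significant"] = bh_fdr(posthoc["p"], config.alpha)
    table.attrs["posthoc"] = posthoc
    return table


def run_full_analysis(
    ibs_table: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    config: StatsConfig | None = None,
) -> dict:
    """The complete statistical stage on tidy tables.

    Parameters
    ----------
    ibs_table : columns (dyad_id, group, task, channel_pair, z).
    metrics : optional, columns (dyad_id, group, mlu, tnw, wps, cps).
    scores : optional, columns (dyad_id, group, symptom_total, task_score, ...).
    config : thresholds, test variants and the correlation group.

    Returns a dict with per-task channel comparison tables (with attached
    post-hoc frames), the metric comparison table, and Kendall correlations
    between flagged-channel IBS and the metric/score columns within the
    configured clinical group.
    """
    config = config or StatsConfig()
    report: dict = {"channel_comparisons": {}, "correlations": None}
    flagged: list[tuple[str, object]] = []
    for task, sub in ibs_table.groupby("task"):
        table = group_comparison_table(sub, "z", "channel_pair", config)
        report["channel_comparisons"][task] = table
        for _, row in table[table["significant"]].iterrows():
            flagged.append((task, row["channel_pair"]))

    if metrics is not None:
        long = metrics.melt(
            id_vars=[c for c in ("dyad_id", "group") if c in metrics.columns],
            var_name="metric",
            value_name="value",
        )
        report["metric_comparisons"] = group_comparison_table(
            long, "value", "metric", config
        )

    # Kendall correlations restricted to channels flagged in the group stage
    corr_rows = []
    candidates: list[pd.DataFrame] = []
    if metrics is not None:
        candidates.append(metrics)
    if scores is not None:
        candidates.append(scores)
    if flagged and candidates:
        clin = ibs_table[ibs_table["group"] == config.correlation_group]
        for task, pair in flagged:
            z = clin[(clin["task"] == task) & (clin["channel_pair"] == pair)]
            z = z.set_index("dyad_id")["z"]
            for frame in candidates:
                value_cols = [
                    c
                    for c in frame.columns
                    if c not in ("dyad_id", "group")
                    and pd.api.types.is_numeric_dtype(frame[c])
                ]
                sub = frame[frame["group"] == config.correlation_group]
                sub = sub.set_index("dyad_id")
                for col in value_cols:
                    joined = pd.concat([z, sub[col]], axis=1, join="inner").dropna()
                    if len(joined) < 3:
                        continue
                    try:
                        res = kendall(joined["z"], joined[col])
                    except ValueError:
                        continue
                    corr_rows.append(
                        {
                            "task": task,
                            "channel_pair": pair,
                            "variable": col,
                            "tau": res.tau,
                            "p": res.p,
                            "n": res.n,
                        }
                    )
    report["correlations"] = pd.DataFrame(corr_rows)
    return report
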