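"""Hidden-food olfactory assay analysis with motivation/motor controls.

Latency to find a buried piece of chocolate is right-censored at the 600-s
test cap; an animal that never reaches the food counts as a failure.  A
group-by-week effect in the hidden-food task is interpreted as an olfactory
deficit only when the same dataset's visible-food, food-intake, and
weight-gain comparisons are all non-significant — the control logic of the
assay encoded as a pipeline rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .lfpsim import BehaviorStudy

__all__ = [
    "BehaviorDataset",
    "analyze_hidden_food",
    "count_failures",
    "analyze_controls",
    "interpret",
]

_LATENCY_COLS = {"animal_id", "group", "week", "task", "latency_s", "censored"}


@dataclass
class BehaviorDataset:
    """Tidy latency, intake, and weight tables with a common cap."""

    latency: pd.DataFrame
    intake: pd.DataFrame | None = None
    weight: pd.DataFrame | None = None
    cap_s: float = 600.0

    def __post_init__(self) -> None:
        missing = _LATENCY_COLS - set(self.latency.columns)
        if missing:
            raise ValueError(f"latency table is missing columns: {sorted(missing)}")
        if (self.latency["latency_s"] > self.cap_s + 1e-9).any():
            raise ValueError(f"latencies above the {self.cap_s}-s cap")
        bad_weeks = set(self.latency["week"]) - {1, 2, 3, 4}
        if bad_weeks:
            raise ValueError(f"weeks outside 1..4: {sorted(bad_weeks)}")

    @classmethod
    def from_study(cls, study: BehaviorStudy, cap_s: float = 600.0) -> "BehaviorDataset":
        return cls(study.latency, study.intake, study.weight, cap_s)


def count_failures(records: pd.DataFrame, week: int, group: str) -> tuple[int, int]:
    """(failed, total) for one (week, group) cell; a failure is a censored trial."""
    cell = records[(records["week"] == week) & (records["group"] == group)]
    if cell.empty:
        raise ValueError(f"empty cell: week {week}, group {group!r}")
    return int(cell["censored"].sum()), int(len(cell))


def _cell(df: pd.DataFrame, **mask) -> pd.DataFrame:
    out = df
    for col, val in mask.items():
        out = out[out[col] == val]
    return out


def analyze_hidden_food(
    dataset: BehaviorDataset,
    alpha: float = 0.05,
    feeding: str | None = "fed",
    baseline_week: int = 1,
) -> pd.DataFrame:
    """Per-week hidden-food comparison table.

    For each week: censoring-aware group medians + IQR, failure counts,
    the between-group rank test (two-group Kruskal-Wallis), and each group's
    paired Wilcoxon comparison against its own baseline week.
    """
    hidden = dataset.latency[dataset.latency["task"] == "hidden"]
    if "cohort" in hidden.columns:
        hidden = hidden[hidden["cohort"] == "main"]
    if feeding is not None and "feeding" in hidden.columns:
        hidden = hidden[hidden["feeding"] == feeding]
    groups = sorted(hidden["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    weeks = sorted(hidden["week"].unique())
    rows = []
    for week in weeks:
        cells = {}
        for g in groups:
            cell = _cell(hidden, week=week, group=g)
            if cell.empty:
                raise ValueError(f"missing cell: week {week}, group {g!r}")
            cells[g] = cell
        between = stats.kruskal_wallis([cells[g]["latency_s"].to_numpy() for g in groups])
        row: dict = {"week": week, "between_group_p": between.p_value,
                     "between_group_stat": between.statistic,
                     "significant": between.p_value < alpha}
        for g in groups:
            summ = stats.summarize(
                cells[g]["latency_s"].to_numpy(),
                cells[g]["censored"].to_numpy(),
                dataset.cap_s,
            )
            failed, total = count_failures(hidden, week, g)
            row.update(
                {
                    f"{g}_median_s": summ.median,
                    f"{g}_iqr_lo_s": summ.iqr_lo,
                    f"{g}_iqr_hi_s": summ.iqr_hi,
                    f"{g}_mean_s": summ.mean,
                    f"{g}_sem_s": summ.sem,
                    f"{g}_failed": failed,
                    f"{g}_n": total,
                    f"{g}_median_is_lower_bound": summ.median_is_lower_bound,
                }
            )
            # within-group comparison against the baseline week, paired by animal
            if week == baseline_week:
                row[f"{g}_vs_week{baseline_week}_p"] = float("nan")
            else:
                base = _cell(hidden, week=baseline_week, group=g).set_index("animal_id")
                cur = cells[g].set_index("animal_id")
                common = base.index.intersection(cur.index)
                if len(common) >= 3:
                    res = stats.wilcoxon_signed_rank(
                        cur.loc[common, "latency_s"].to_numpy(),
                        base.loc[common, "latency_s"].to_numpy(),
                    )
                    row[f"{g}_vs_week{baseline_week}_p"] = res.p_value
                else:
                    row[f"{g}_vs_week{baseline_week}_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_controls(dataset: BehaviorDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Group comparisons for the motivation and motor controls.

    Visible-food latency (per feeding stratum), food intake at each window,
    and weekly weight gain, each with the same rank test and censoring-aware
    summaries as the main analysis.
    """
    rows = []

    visible = dataset.latency[dataset.latency["task"] == "visible"]
    if visible.empty:
        raise ValueError("missing table: visible-food latencies")
    strata = sorted(visible["feeding"].unique()) if "feeding" in visible.columns else [None]
    for stratum in strata:
        sub = visible if stratum is None else visible[visible["feeding"] == stratum]
        groups = sorted(sub["group"].unique())
        res = stats.kruskal_wallis([_cell(sub, group=g)["latency_s"].to_numpy() for g in groups])
        rows.append(
            {
                "comparison": f"visible_latency[{stratum or 'all'}]",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )

    if dataset.intake is None:
        raise ValueError("missing table: intake")
    for window in sorted(dataset.intake["window_min"].unique()):
        sub = dataset.intake[dataset.intake["window_min"] == window]
        groups = sorted(sub["group"].unique())
        res = stats.kruskal_wallis([_cell(sub, group=g)["grams"].to_numpy() for g in groups])
        rows.append(
            {
                "comparison": f"intake_{int(window)}min",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )

    if dataset.weight is None:
        raise ValueError("missing table: weight")
    for week in sorted(dataset.weight["week"].unique()):
        sub = dataset.weight[dataset.weight["week"] == week]
        groups = sorted(sub["group"].unique())
        res = stats.kruskal_wallis(
            [_cell(sub, group=g)["pct_of_baseline"].to_numpy() for g in groups]
        )
        rows.append(
            {
                "comparison": f"weight_week{int(week)}",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


def interpret(hidden_table: pd.DataFrame, controls_table: pd.DataFrame) -> str:
    """Apply the assay's control logic to the two analysis tables.

    Returns "olfactory deficit" only when at least one week shows a
    significant hidden-food group difference AND every control comparison is
    non-significant; a significant control renders the hidden-food effect
    "confounded"; otherwise "no deficit detected".
    """
    hidden_effect = bool(hidden_table["significant"].any())
    controls_clean = not bool(controls_table["significant"].any())
    if hidden_effect and controls_clean:
        return "olfactory deficit"
    if hidden_effect:
        return "confounded"
    return "no deficit detected"
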