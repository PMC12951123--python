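"""Descriptive result tables: trend composition by clade and trend-by-threat
cross-tabulations, each emitted as machine-readable data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import THREAT_LEVELS, TREND_LEVELS


@dataclass
class TrendSummary:
    """Counts and proportions per trend class, per group and overall.

    Groups with at most ``min_group`` species are excluded from the per-group
    listing but still counted in the totals.
    """

    per_group: pd.DataFrame       # index group; count cols + prop cols
    totals: pd.Series
    min_group: int
    n_groups_listed: int
    n_groups_suppressed: int


def trend_summary(table: pd.DataFrame, group_column: str = "family",
                  min_group: int = 10) -> TrendSummary:
    """Per-group composition of population trends.

    Mirrors the family-level decline summaries: only groups with more than
    ``min_group`` species are listed individually.
    """
    if table.empty:
        raise ValueError("empty species table")
    trend = table["trend"].fillna("unknown")
    counts = (
        pd.crosstab(table[group_column], trend)
        .reindex(columns=TREND_LEVELS, fill_value=0)
    )
    totals = trend.value_counts().reindex(TREND_LEVELS, fill_value=0)
    keep = counts.sum(axis=1) > min_group
    listed = counts.loc[keep].copy()
    props = listed.div(listed.sum(axis=1), axis=0)
    per_group = pd.concat(
        [listed, props.add_prefix("prop_")], axis=1
    )
    per_group["prop_declining"] = props["decreasing"]
    return TrendSummary(
        per_group=per_group.sort_values("prop_declining", ascending=False),
        totals=totals,
        min_group=min_group,
        n_groups_listed=int(keep.sum()),
        n_groups_suppressed=int((~keep).sum()),
    )


def crosstab_trend_threat(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Trend x threat-category contingency table with conditional percentages.

    ``row_pct`` conditions on trend (e.g., the share of declining species that
    are Least Concern); ``col_pct`` conditions on threat category (e.g., the
    share of Data Deficient species that are declining). Empty categories get
    zero rows with percentages defined as 0.
    """
    for col in ("trend", "threat_category"):
        if col not in table.columns:
            raise ValueError(f"table has no {col} column")
    counts = (
        pd.crosstab(table["trend"].fillna("unknown"),
                    table["threat_category"].fillna("DD"))
        .reindex(index=TREND_LEVELS, columns=THREAT_LEVELS, fill_value=0)
    )
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    row_pct = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0) * 100
    col_pct = counts.div(col_sums.replace(0, np.nan), axis=1).fillna(0) * 100
    return {"counts": counts, "row_pct": row_pct, "col_pct": col_pct}
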