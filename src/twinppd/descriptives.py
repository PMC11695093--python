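"""Cohort characteristic tables (counts, percentages, medians/IQRs).

Summaries follow registry-table conventions: parent-level variables use
role-specific parent counts as denominators, childbirth-level variables
use unique childbirth counts; missing values are excluded from numerators
but kept in denominators; percentages are rounded half-up to one decimal;
medians and quartiles use (n+1)-position linear interpolation between
order statistics (Hyndman-Fan type 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = ["percentage", "median_iqr", "summarize_cohort", "CohortSummary",
           "CALENDAR_PERIODS"]

CALENDAR_PERIODS = ((1997, 2004), (2005, 2011), (2012, 2019))

#: childbirth-level flag columns summarized when present in the births table
BIRTH_FLAG_COLUMNS = (
    "art_flag",
    "preterm_flag",
    "csection_flag",
    "preeclampsia_flag",
    "gestational_diabetes_flag",
    "hemorrhage_flag",
    "nicu_flag",
)


def percentage(count: float, denominator: float, dp: int = 1) -> float:
    """100 * count / denominator, rounded half-up to ``dp`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    pct = Decimal(100 * count) / Decimal(denominator)
    q = Decimal(1).scaleb(-dp)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the (n+1)-rule linear interpolation."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no non-missing values")
    med, q1, q3 = np.percentile(x, [50, 25, 75], method="weibull")
    return float(med), float(q1), float(q3)


@dataclass
class CohortSummary:
    """Nested summary: ``parents[role][plurality]`` and
    ``childbirths[plurality]`` blocks of counts/percentages."""

    parents: dict = field(default_factory=dict)
    childbirths: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, by_pl in self.parents.items():
            for pl, stats in by_pl.items():
                for key, val in stats.items():
                    rows.append({"level": role, "plurality": pl, "variable": key, "value": val})
        for pl, stats in self.childbirths.items():
            for key, val in stats.items():
                rows.append({"level": "childbirth", "plurality": pl, "variable": key, "value": val})
        return pd.DataFrame(rows)

    def render(self) -> str:
        df = self.to_frame()
        lines = []
        for (level, pl), grp in df.groupby(["level", "plurality"], sort=False):
            lines.append(f"[{level} / {pl}]")
            for _, r in grp.iterrows():
                lines.append(f"  {r['variable']}: {r['value']}")
        return "\n".join(lines)


def _flag_stats(frame: pd.DataFrame, col: str, denom: int) -> tuple[int, float]:
    n = int(pd.to_numeric(frame[col], errors="coerce").fillna(0).astype(float).eq(1.0).sum())
    return n, percentage(n, denom)


def summarize_cohort(records: pd.DataFrame, registry=None) -> CohortSummary:
    """Characteristics of the eligible cohort by role and plurality.

    ``records`` is the follow-up table from the cohort builder.  Parent
    blocks report n, age median (IQR), calendar-period counts, and the
    cohabiting/primiparous shares; the childbirth block (unique birth ids,
    mothers' rows preferred as the covariate source) reports whichever of
    the known obstetric flag columns are present.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    summary = CohortSummary()
    for role, by_role in records.groupby("role"):
        summary.parents[role] = {}
        for pl, grp in by_role.groupby("plurality"):
            n = len(grp)
            med, q1, q3 = median_iqr(grp["age_years"].to_numpy())
            stats = {
                "n": n,
                "age_median": med,
                "age_q1": q1,
                "age_q3": q3,
            }
            for lo, hi in CALENDAR_PERIODS:
                cnt = int(grp["calendar_year"].between(lo, hi).sum())
                stats[f"year_{lo}_{hi}_n"] = cnt
                stats[f"year_{lo}_{hi}_pct"] = percentage(cnt, n)
            cnt, pct = _flag_stats(grp, "cohabiting_flag", n)
            stats["cohabiting_n"], stats["cohabiting_pct"] = cnt, pct
            if role == "mother":
                cnt, pct = _flag_stats(grp, "primiparous_flag", n)
                stats["primiparous_n"], stats["primiparous_pct"] = cnt, pct
            summary.parents[role][pl] = stats

    # childbirth level: one row per unique birth id (mothers' rows carry
    # the full covariate set, so prefer them)
    births = (
        records.sort_values("role", kind="stable", ascending=False)
        .drop_duplicates("birth_id", keep="first")
    )
    for pl, grp in births.groupby("plurality"):
        n = len(grp)
        stats = {"n": n}
        for col in BIRTH_FLAG_COLUMNS:
            if col in grp.columns:
                cnt, pct = _flag_stats(grp, col, n)
                stats[f"{col}_n"], stats[f"{col}_pct"] = cnt, pct
        summary.childbirths[pl] = stats
    return summary
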