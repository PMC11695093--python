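"""Cohort construction: washout, exposure labelling, first-event outcome.

Turns raw register tables into one follow-up record per eligible
parent-birth.  A parent-birth is eligible unless the parent has a
qualifying depression diagnosis or antidepressant prescription during the
washout window before childbirth (default two years).  The outcome is the
first qualifying event from the day of childbirth through the 365-day
horizon; parents with no event are censored at the horizon.  Mothers and
fathers are screened independently, so the two eligible populations can
differ in size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RawRegistry

__all__ = ["CodeRules", "apply_washout", "derive_outcome", "restrict_cohort", "build_cohort"]

ROLES = ("mother", "father")

#: FollowUpRecord columns produced by :func:`derive_outcome`.
RECORD_COLUMNS = [
    "birth_id",
    "parent_id",
    "role",
    "plurality",
    "entry_day",
    "exit_day",
    "event_flag",
    "event_kind",
    "age_years",
    "calendar_year",
    "art_flag",
    "cohabiting_flag",
    "primiparous_flag",
]


@dataclass(frozen=True)
class CodeRules:
    """Outcome/washout definition.

    ``diagnosis_prefixes``/``prescription_prefixes`` are matched against
    event code strings by prefix after upper-casing and stripping dots
    (both plain ICD-10 "F32" and Danish-dialect "DF32" spellings accepted
    by default).  ``outcome_mode`` restricts which event kinds count as the
    outcome; the washout always screens on both code families, since the
    washout defines new-onset depression regardless of how the outcome is
    measured.
    """

    diagnosis_prefixes: tuple[str, ...] = ("F32", "F33", "DF32", "DF33")
    prescription_prefixes: tuple[str, ...] = ("N06A",)
    washout_days: int = 730
    horizon_days: int = 365
    outcome_mode: str = "composite"
    year_restriction: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.washout_days <= 0 or self.horizon_days <= 0:
            raise ValueError("washout_days and horizon_days must be positive")
        if not self.diagnosis_prefixes or not self.prescription_prefixes:
            raise ValueError("prefix lists must be non-empty")
        if self.outcome_mode not in ("composite", "diagnosis_only", "prescription_only"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")


def _normalize_codes(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.upper().str.replace(".", "", regex=False)


def _match_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    norm = _normalize_codes(codes)
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= norm.str.startswith(p.upper().replace(".", ""))
    return out


def _qualifying_events(events: pd.DataFrame, rules: CodeRules, mode: str) -> pd.DataFrame:
    """Events whose code matches the prefixes relevant for ``mode``."""
    is_dx = _match_prefix(events["code"], rules.diagnosis_prefixes)
    is_rx = _match_prefix(events["code"], rules.prescription_prefixes)
    if mode == "washout" or mode == "composite":
        keep = is_dx | is_rx
    elif mode == "diagnosis_only":
        keep = is_dx
    elif mode == "prescription_only":
        keep = is_rx
    else:  # pragma: no cover - guarded by CodeRules
        raise ValueError(mode)
    out = events.loc[keep].copy()
    out["matched_kind"] = np.where(is_dx[keep], "diagnosis", "prescription")
    return out


def _check_births(births: pd.DataFrame) -> pd.DataFrame:
    bad = ~births["role"].isin(ROLES)
    if bad.any():
        raise ValueError(
            f"unknown role(s) {sorted(births.loc[bad, 'role'].unique())} in births table"
        )
    births = births.copy()
    births["birth_date"] = _parse_dates(births["birth_date"], "births")
    return births


def _parse_dates(col: pd.Series, table: str) -> pd.Series:
    parsed = pd.to_datetime(col, errors="coerce")
    if parsed.isna().any():
        rows = list(col.index[parsed.isna()][:5])
        raise ValueError(f"unparseable date(s) in {table} table at rows {rows}")
    return parsed


def apply_washout(registry: RawRegistry, rules: CodeRules) -> pd.DataFrame:
    """Return eligible (parent_id, birth_id, role) rows after washout.

    A parent-birth is excluded iff the parent has any qualifying event
    (either code family) dated within ``[birth - washout_days, birth - 1]``
    days — the birth date itself never triggers washout; an event on the
    birth date counts as a postpartum outcome instead.
    """
    births = _check_births(registry.births)
    events = registry.events.copy()
    events["event_date"] = _parse_dates(events["event_date"], "events")
    q = _qualifying_events(events, rules, "washout")

    merged = births[["birth_id", "parent_id", "role", "birth_date"]].merge(
        q[["parent_id", "event_date"]], on="parent_id", how="left"
    )
    delta = (merged["event_date"] - merged["birth_date"]).dt.days
    hit = (delta >= -rules.washout_days) & (delta <= -1)
    excluded = merged.loc[hit, ["parent_id", "birth_id"]].drop_duplicates()
    key = births[["parent_id", "birth_id", "role"]].merge(
        excluded.assign(_excl=True), on=["parent_id", "birth_id"], how="left"
    )
    return (
        key.loc[key["_excl"].isna(), ["parent_id", "birth_id", "role"]]
        .reset_index(drop=True)
    )


def derive_outcome(
    eligible: pd.DataFrame, registry: RawRegistry, rules: CodeRules
) -> pd.DataFrame:
    """Build follow-up records (first qualifying event or censoring).

    The event day is the minimum qualifying post-birth day in
    ``[0, horizon]``; a recorded integer day ``d`` maps to a continuous
    exit time ``d + 0.5`` (mid-day convention, capped at the horizon), so
    same-day events carry positive risk time.  A diagnosis and a
    prescription on the same day resolve to a diagnosis (severity-first
    tie-break).  Parents with no qualifying event are censored at exactly
    the horizon.
    """
    births = _check_births(registry.births)
    events = registry.events.copy()
    events["event_date"] = _parse_dates(events["event_date"], "events")
    q = _qualifying_events(events, rules, rules.outcome_mode)

    base = births.merge(eligible, on=["parent_id", "birth_id", "role"], how="inner")
    merged = base[["birth_id", "parent_id", "birth_date"]].merge(
        q[["parent_id", "event_date", "matched_kind"]], on="parent_id", how="left"
    )
    merged["day"] = (merged["event_date"] - merged["birth_date"]).dt.days
    merged = merged[(merged["day"] >= 0) & (merged["day"] <= rules.horizon_days)]
    # first event; diagnosis wins a same-day tie ("diagnosis" < "prescription")
    merged = merged.sort_values(
        ["birth_id", "parent_id", "day", "matched_kind"], kind="stable"
    )
    first = merged.groupby(["birth_id", "parent_id"], as_index=False).first()

    rec = base.merge(
        first[["birth_id", "parent_id", "day", "matched_kind"]],
        on=["birth_id", "parent_id"],
        how="left",
    )
    has_event = rec["day"].notna()
    rec["entry_day"] = 0.0
    rec["exit_day"] = np.where(
        has_event,
        np.minimum(rec["day"].fillna(0) + 0.5, float(rules.horizon_days)),
        float(rules.horizon_days),
    )
    rec["event_flag"] = has_event
    rec["event_kind"] = rec["matched_kind"].fillna("none")
    rec = rec[RECORD_COLUMNS].sort_values(
        ["role", "birth_id", "parent_id"], kind="stable"
    )
    return rec.reset_index(drop=True)


def restrict_cohort(records: pd.DataFrame, rules: CodeRules) -> pd.DataFrame:
    """Keep records with calendar_year inside ``rules.year_restriction``.

    Identity when no restriction is set; warns (never errors) if the
    restriction empties the cohort.
    """
    if rules.year_restriction is None:
        return records
    lo, hi = rules.year_restriction
    out = records[
        (records["calendar_year"] >= lo) & (records["calendar_year"] <= hi)
    ].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(
            f"year restriction {lo}-{hi} removed every record", stacklevel=2
        )
    return out


def build_cohort(
    registry: RawRegistry, rules: CodeRules | None = None, role: str | None = None
) -> pd.DataFrame:
    """Washout -> outcome -> restriction, optionally for a single role."""
    rules = rules or CodeRules()
    eligible = apply_washout(registry, rules)
    if role is not None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        eligible = eligible[eligible["role"] == role]
    records = derive_outcome(eligible, registry, rules)
    return restrict_cohort(records, rules)
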