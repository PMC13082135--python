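"""Time-to-initiation outcome derivation from visit-level endorsement items.

Harmonizes annual-assessment and interim phone-interview endorsement tables,
masks endorsements that occurred exclusively in religious/ceremonial
contexts, and scans each participant's ordered visits for the first
affirmative endorsement.  Follow-up is censored at the 4-year visit; control
status additionally requires a documented observation at the 3-year
follow-up, otherwise the case-control status is coded missing (the censored
survival record is still usable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default visit ordering: baseline < mid-year phone < annual follow-ups
DEFAULT_VISIT_ORDER = (
    "baseline", "phone_06", "fu1", "phone_18", "fu2",
    "phone_30", "fu3", "phone_42", "fu4",
)


class SchemaError(ValueError):
    pass


@dataclass
class OutcomeSpec:
    """Which items define initiation of one substance (or a union)."""

    name: str
    items: list[str]
    religious_flags: dict[str, str] = field(default_factory=dict)  # item -> flag column
    censor_visit: str = "fu4"
    control_visit: str = "fu3"

    def __post_init__(self):
        if not self.items:
            raise SchemaError(f"outcome {self.name}: empty item set")
        for item in self.religious_flags:
            if item not in self.items:
                raise SchemaError(
                    f"outcome {self.name}: religious flag refers to unknown item {item!r}"
                )


def union_spec(name: str, specs: list[OutcomeSpec]) -> OutcomeSpec:
    """'Any substance' style union of several per-substance item sets."""
    items, flags = [], {}
    for s in specs:
        items.extend(i for i in s.items if i not in items)
        flags.update(s.religious_flags)
    base = specs[0]
    return OutcomeSpec(name=name, items=items, religious_flags=flags,
                       censor_visit=base.censor_visit, control_visit=base.control_visit)


def coerce_binary(series: pd.Series) -> pd.Series:
    """Coerce responses to {0, 1}; anything else (e.g. refuse codes) -> missing."""
    s = pd.to_numeric(series, errors="coerce")
    return s.where(s.isin([0.0, 1.0]))


def harmonize_sources(
    annual: pd.DataFrame,
    phone: pd.DataFrame | None,
    item_cols: list[str],
    visit_order=DEFAULT_VISIT_ORDER,
) -> pd.DataFrame:
    """Merge the two endorsement sources and order observations by study visit.

    Both tables need ``id`` and ``visit`` columns; item responses are coerced
    to valid binary values with invalid codes set to missing.  Unknown visit
    labels raise a :class:`SchemaError` naming them.
    """
    frames = [annual]
    if phone is not None and len(phone):
        frames.append(phone)
    df = pd.concat(frames, ignore_index=True, sort=False)
    order = {lab: i for i, lab in enumerate(visit_order)}
    unknown = sorted(set(df["visit"]) - set(order))
    if unknown:
        raise SchemaError(f"unknown visit label(s): {unknown}")
    for col in item_cols:
        if col in df.columns:
            df[col] = coerce_binary(df[col])
    df = df.assign(_order=df["visit"].map(order))
    df = df.sort_values(["id", "_order"], kind="stable").drop(columns="_order")
    return df.reset_index(drop=True)


def mask_religious_context(table: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Set endorsements flagged as exclusively-religious-context to missing."""
    out = table.copy()
    for item, flag in spec.religious_flags.items():
        if flag not in out.columns:
            continue
        hit = (out[item] == 1) & (out[flag] == 1)
        out.loc[hit, item] = np.nan
    return out


def derive_outcome(
    table: pd.DataFrame,
    spec: OutcomeSpec,
    tracking: pd.DataFrame | None = None,
    visit_order=DEFAULT_VISIT_ORDER,
    t_zero_event: float = 0.5,
) -> pd.DataFrame:
    """Per-participant survival outcome for one substance.

    Scans visits in study order (through the censor visit) for the first
    affirmative endorsement among the spec's items, skipping missing
    responses.  Event time is months since baseline at that visit (a
    baseline endorsement is retained as an event at ``t_zero_event`` months
    so the risk set is non-degenerate).  Non-initiators are censored at
    their last observed visit on/before the censor visit; control status
    requires observation at the control visit, otherwise status is missing.

    ``tracking`` optionally supplies ``interview_age_months`` per
    (id, visit); by default the endorsement table's own column is used.

    Returns a DataFrame with columns ``id, T, event, status``.
    """
    order = {lab: i for i, lab in enumerate(visit_order)}
    censor_ord = order[spec.censor_visit]
    control_ord = order[spec.control_visit]
    src = table
    if tracking is not None:
        src = table.drop(columns=["interview_age_months"], errors="ignore").merge(
            tracking[["id", "visit", "interview_age_months"]], on=["id", "visit"], how="left"
        )
    src = src.assign(_order=src["visit"].map(order))
    if src["_order"].isna().any():
        bad = sorted(set(src.loc[src["_order"].isna(), "visit"]))
        raise SchemaError(f"unknown visit label(s): {bad}")
    src = src[src["_order"] <= censor_ord]
    src = src.sort_values(["id", "_order"], kind="stable")

    items = [c for c in spec.items if c in src.columns]
    if not items:
        raise SchemaError(f"outcome {spec.name}: none of the items present in table")

    records = []
    n_excluded = 0
    for pid, g in src.groupby("id", sort=False):
        ages = g["interview_age_months"].to_numpy(dtype=float)
        if g.empty or np.isnan(ages).all():
            n_excluded += 1
            continue
        base_age = ages[~np.isnan(ages)][0]
        months = ages - base_age
        vals = g[items].to_numpy(dtype=float)
        affirmative = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=1) == 1.0
        if affirmative.any():
            first = int(np.argmax(affirmative))
            T = float(months[first])
            if T <= 0:
                T = t_zero_event
            records.append({"id": pid, "T": T, "event": 1, "status": "case"})
        else:
            obs_months = months[~np.isnan(months)]
            T = float(obs_months[-1]) if obs_months.size else 0.0
            has_control_visit = (g["_order"] == control_ord).any()
            status = "control" if has_control_visit else "missing"
            records.append({"id": pid, "T": T, "event": 0, "status": status})
    if n_excluded:
        logger.info("derive_outcome[%s]: excluded %d participants with no usable visits",
                    spec.name, n_excluded)
    return pd.DataFrame.from_records(records, columns=["id", "T", "event", "status"])
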