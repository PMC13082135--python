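"""Counting-process (start-stop) interval construction.

Converts per-participant visit records into the interval layout time-varying
Cox models require: each participant contributes rows [start, stop) with
covariates frozen at the interval start, and the event indicator set only on
the final interval.  Covariate carry-forward is strictly last-observation-
carried-forward within participant (never backward), so no row can see
information from a later visit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class IntervalError(ValueError):
    pass


def compute_time_months(interview_age_months: float, baseline_age_months: float) -> float:
    """Follow-up time in months since baseline for one visit."""
    if interview_age_months < 0 or baseline_age_months < 0:
        raise IntervalError("ages must be non-negative")
    t = interview_age_months - baseline_age_months
    if t < 0:
        raise IntervalError(
            f"visit predates baseline (interview age {interview_age_months} "
            f"< baseline age {baseline_age_months})"
        )
    return t


def _interval_rows(visit_times, T: float) -> list[tuple[float, float, int]]:
    """(start, stop, source_visit_index) triples before event assignment.

    ``source_visit_index`` indexes the input visit list and says which
    visit's covariates the interval freezes; a synthetic baseline row at
    time 0 copies the earliest observation (index 0).
    """
    if T < 0:
        raise IntervalError("follow-up time T must be >= 0")
    vt = list(visit_times)
    if not vt:
        raise IntervalError("empty visit list")
    if any(b < a for a, b in zip(vt, vt[1:])):
        raise IntervalError("visit times must be sorted ascending")
    if vt[-1] > T:
        raise IntervalError("visit time exceeds follow-up time T")
    starts = list(vt)
    src = list(range(len(vt)))
    if vt[0] > 0:
        starts = [0.0] + starts  # baseline row at time 0 copying the earliest observation
        src = [0] + src
    stops = starts[1:] + [T]
    return [(s, e, k) for s, e, k in zip(starts, stops, src) if e > s]


def build_intervals(visit_times, T: float, event: int) -> list[tuple[float, float, int]]:
    """Start-stop rows ``(start, stop, event_interval)`` for one participant.

    Rows follow the counting-process recipe: the i-th interval runs from the
    i-th visit time (0 for the first) to the next visit time, and the last
    runs to the follow-up time ``T``; the event can only sit on the final
    interval; zero-length intervals (stop <= start) are dropped.  If the
    first visit is after time 0, a synthetic baseline row anchored at 0 is
    prepended (carrying the earliest observation's covariates downstream).
    """
    rows = [(s, e, 0) for s, e, _ in _interval_rows(visit_times, T)]
    if rows and event:
        s, e, _ = rows[-1]
        rows[-1] = (s, e, 1)
    return rows


def forward_fill(long_table: pd.DataFrame, columns: list[str], id_col: str = "id",
                 time_col: str = "time") -> pd.DataFrame:
    """Within-participant LOCF on ``columns``; no back-filling.

    Rows must be sorted by (id, time); a sorted copy is made if not.
    """
    df = long_table
    if not df[[id_col, time_col]].apply(tuple, axis=1).is_monotonic_increasing:
        df = df.sort_values([id_col, time_col], kind="stable")
    out = df.copy()
    out[columns] = out.groupby(id_col, sort=False)[columns].ffill()
    return out


def encode_value_availability(
    long_table: pd.DataFrame, predictors: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Value + availability encoding of intermittently missing predictors.

    For each predictor ``X`` adds ``X_obs`` (1 if the — possibly forward
    filled — value is observed, 0 otherwise) and fills missing values with
    the median of observed cells, pooled over all participants and visits.
    Predictors with zero observed cells are dropped with a warning (their
    median is undefined).  Returns the encoded table and the list of kept
    predictors.
    """
    out = long_table.copy()
    kept = []
    for col in predictors:
        obs = out[col].notna()
        if not obs.any():
            logger.warning("encode_value_availability: %s has no observed values; dropped", col)
            out = out.drop(columns=[col])
            continue
        med = float(out.loc[obs, col].median())
        out[col + "_obs"] = obs.astype(int)
        out[col] = out[col].fillna(med)
        kept.append(col)
    return out, kept


def build_interval_table(
    long_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariate_cols: list[str],
    *,
    id_col: str = "id",
    time_col: str = "time",
) -> pd.DataFrame:
    """Assemble the full counting-process table for a cohort.

    ``long_table`` holds one row per participant-visit with ``time`` in
    months since baseline and covariate columns (already forward-filled /
    encoded as desired).  ``outcomes`` holds one row per participant with
    ``T`` (months) and ``event``; participants whose status is missing should
    be excluded upstream.  Covariates are frozen at the interval start; when
    an event time ties with a visit time the value from the earlier visit is
    used (no look-ahead).
    """
    frames = []
    out_idx = outcomes.set_index(id_col)
    grouped = long_table.sort_values([id_col, time_col], kind="stable").groupby(id_col, sort=False)
    n_skipped = 0
    for pid, g in grouped:
        if pid not in out_idx.index:
            n_skipped += 1
            continue
        T = float(out_idx.at[pid, "T"])
        event = int(out_idx.at[pid, "event"])
        g = g[g[time_col] < T]  # a visit at exactly T starts a zero-length interval
        if g.empty:
            # participant's only usable observation is the earliest visit overall
            g = long_table[long_table[id_col] == pid].sort_values(time_col).head(1)
            if g.empty or T <= 0:
                n_skipped += 1
                continue
        times = g[time_col].to_numpy(dtype=float)
        rows = _interval_rows(times, T)
        if not rows:
            n_skipped += 1
            continue
        covs = g[covariate_cols].to_numpy()
        take = [k for _, _, k in rows]
        block = pd.DataFrame(covs[take], columns=covariate_cols)
        block.insert(0, id_col, pid)
        block.insert(1, "start", [r[0] for r in rows])
        block.insert(2, "stop", [r[1] for r in rows])
        block.insert(3, "event_interval", 0)
        if event:
            block.iloc[-1, block.columns.get_loc("event_interval")] = 1
        frames.append(block)
    if n_skipped:
        logger.info("build_interval_table: skipped %d participants without usable follow-up",
                    n_skipped)
    if not frames:
        return pd.DataFrame(columns=[id_col, "start", "stop", "event_interval", *covariate_cols])
    return pd.concat(frames, ignore_index=True)
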