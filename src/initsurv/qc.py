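"""Minimal predictor filtering applied before modeling.

Four filters: drop entirely-missing columns, drop near-constant numeric
columns, drop one member of each highly correlated pair (|Pearson r| above a
threshold, pairwise-complete), and a coverage filter requiring a predictor
be observed at least once in at least half the participants.  Forced
covariates (sex, age, site, PCs) and polygenic scores are exempt; pass them
via ``exempt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class QCReport:
    """Per-predictor disposition after a QC pass."""

    disposition: dict[str, str] = field(default_factory=dict)
    collinear_partner: dict[str, tuple[str, float]] = field(default_factory=dict)

    def kept(self) -> list[str]:
        return [c for c, d in self.disposition.items() if d == "kept"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col, disp in self.disposition.items():
            partner, r = self.collinear_partner.get(col, (None, np.nan))
            rows.append({"predictor": col, "disposition": disp,
                         "partner": partner, "abs_r": r})
        return pd.DataFrame(rows)


def drop_all_missing(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, QCReport]:
    report = QCReport()
    drop = []
    for c in columns:
        if table[c].notna().sum() == 0:
            report.disposition[c] = "all_missing"
            drop.append(c)
        else:
            report.disposition[c] = "kept"
    return table.drop(columns=drop), report


def drop_near_constant(
    table: pd.DataFrame, columns: list[str], freq_threshold: float = 0.99
) -> tuple[pd.DataFrame, QCReport]:
    """Drop numeric columns whose modal value frequency >= ``freq_threshold``."""
    if not 0.5 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must be in (0.5, 1]")
    report = QCReport()
    drop = []
    for c in columns:
        s = table[c].dropna()
        if len(s) == 0:
            report.disposition[c] = "kept"
            continue
        modal_freq = s.value_counts(normalize=True).iloc[0]
        if modal_freq >= freq_threshold:
            report.disposition[c] = "near_constant"
            drop.append(c)
        else:
            report.disposition[c] = "kept"
    return table.drop(columns=drop), report


def drop_collinear(
    table: pd.DataFrame, columns: list[str], r_threshold: float = 0.9
) -> tuple[pd.DataFrame, QCReport]:
    """Greedy removal of highly correlated predictors.

    Pairs with pairwise-complete |Pearson r| > threshold are visited in
    descending |r|; if both members are still kept, the later column in
    input order is dropped (deterministic tie-break).
    """
    report = QCReport({c: "kept" for c in columns})
    if len(columns) < 2:
        return table, report
    corr = table[columns].corr().abs()
    pairs = []
    for a, b in combinations(columns, 2):
        r = corr.at[a, b]
        if np.isfinite(r) and r > r_threshold:
            pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], columns.index(t[1]), columns.index(t[2])))
    drop = set()
    for r, a, b in pairs:
        if a in drop or b in drop:
            continue
        later = b if columns.index(b) > columns.index(a) else a
        keeper = a if later is b else b
        drop.add(later)
        report.disposition[later] = "collinear_dropped"
        report.collinear_partner[later] = (keeper, float(r))
    return table.drop(columns=sorted(drop)), report


def coverage_fraction(
    long_table: pd.DataFrame, predictors: list[str], id_col: str = "id"
) -> dict[str, float]:
    """Fraction of participants with >= 1 observed (pre-imputation) value."""
    n_ids = long_table[id_col].nunique()
    out = {}
    grouped = long_table.groupby(id_col, sort=False)
    for c in predictors:
        out[c] = float((grouped[c].count() > 0).sum() / n_ids) if n_ids else 0.0
    return out


def coverage_filter(
    long_table: pd.DataFrame,
    predictors: list[str],
    min_frac: float = 0.5,
    id_col: str = "id",
) -> tuple[list[str], QCReport]:
    """Keep predictors observed at least once in >= ``min_frac`` of participants."""
    frac = coverage_fraction(long_table, predictors, id_col)
    report = QCReport()
    kept = []
    for c in predictors:
        if frac[c] >= min_frac:
            report.disposition[c] = "kept"
            kept.append(c)
        else:
            report.disposition[c] = "low_coverage"
    return kept, report


def run_qc(
    long_table: pd.DataFrame,
    predictors: list[str],
    *,
    freq_threshold: float = 0.99,
    r_threshold: float = 0.9,
    min_coverage: float = 0.5,
    id_col: str = "id",
) -> tuple[pd.DataFrame, list[str], QCReport]:
    """Full QC pipeline; returns (filtered table, kept predictors, merged report)."""
    table, rep1 = drop_all_missing(long_table, predictors)
    cols = [c for c in predictors if rep1.disposition[c] == "kept"]
    table, rep2 = drop_near_constant(table, cols, freq_threshold)
    cols = [c for c in cols if rep2.disposition[c] == "kept"]
    table, rep3 = drop_collinear(table, cols, r_threshold)
    cols = [c for c in cols if rep3.disposition[c] == "kept"]
    kept, rep4 = coverage_filter(table, cols, min_coverage, id_col)
    merged = QCReport()
    for rep in (rep1, rep2, rep3, rep4):
        for c, d in rep.disposition.items():
            if merged.disposition.get(c, "kept") == "kept":
                merged.disposition[c] = d
        merged.collinear_partner.update(rep.collinear_partner)
    return table, kept, merged
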