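"""Proportional compression of diagnosis counts to the all-cause consultation total.

Routine facility registers record one row per *diagnosis*, and a sick child
often receives more than one diagnosis per visit, so monthly diagnosis counts
per category sum to more than the number of consultations.  Coverage-change
modelling needs category counts that partition the consultations, so each
cluster-month's category counts are rescaled proportionally to sum exactly to
the all-cause consultation total, with integerisation by largest-remainder
(Hamilton) apportionment.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of a records table that are not diagnosis categories
META_COLUMNS = (
    "cluster_id",
    "pair_id",
    "arm",
    "confounder_score",
    "year",
    "month",
    "month_index",
    "month_of_year",
    "period",
    "all_cause",
)


def category_columns(df: pd.DataFrame) -> list[str]:
    """Diagnosis-category columns of a records table (everything non-meta)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def apportion(counts: Sequence[float], total: int) -> np.ndarray:
    """Allocate an integer ``total`` proportionally to ``counts``.

    Largest-remainder (Hamilton) apportionment: each category receives the
    floor of its exact quota, and the remaining units go to the categories
    with the largest fractional remainders.  Ties are broken by position
    (earlier categories win), which makes the result deterministic.

    With all counts zero, nothing can be allocated and zeros are returned.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative category counts")
    total = int(total)
    if total < 0:
        raise ValueError("negative total")
    s = counts.sum()
    if total == 0 or s == 0:
        return np.zeros(len(counts), dtype=np.int64)
    quota = counts * (total / s)
    base = np.floor(quota).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder > 0:
        # stable argsort on negated remainders -> ties resolved by category order
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def compress_record(record: pd.Series, categories: Iterable[str] | None = None) -> pd.Series:
    """Compress one cluster-month record so category counts sum to ``all_cause``."""
    rec = record.copy()
    if categories is None:
        categories = [c for c in record.index if c not in META_COLUMNS]
    categories = list(categories)
    counts = np.asarray([record[c] for c in categories], dtype=float)
    all_cause = int(record["all_cause"])
    if all_cause < 0:
        raise ValueError("negative all_cause")
    if counts.sum() == 0 and all_cause > 0:
        logger.warning(
            "record with all_cause=%d but zero recorded diagnoses; compressed counts left at 0",
            all_cause,
        )
    rec[categories] = apportion(counts, all_cause)
    return rec


def compress_frame(
    df: pd.DataFrame, categories: Iterable[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Compress every record of a table; returns (compressed table, data-quality report).

    Records with ``all_cause > 0`` but zero recorded diagnoses are retained
    (with zero category counts) and counted in the report.
    """
    if categories is None:
        categories = category_columns(df)
    categories = list(categories)
    counts = df[categories].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative category counts")
    totals = df["all_cause"].to_numpy(dtype=np.int64)
    if np.any(totals < 0):
        raise ValueError("negative all_cause")
    out = np.empty_like(counts, dtype=np.int64)
    for i in range(len(df)):
        out[i] = apportion(counts[i], totals[i])
    res = df.copy()
    res[categories] = out
    n_zero_diag = int(np.sum((counts.sum(axis=1) == 0) & (totals > 0)))
    if n_zero_diag:
        logger.warning("%d records had consultations but no recorded diagnoses", n_zero_diag)
    report = {
        "n_records": int(len(df)),
        "n_zero_diagnosis_records": n_zero_diag,
        "mean_multiplicity_before": float(counts.sum() / totals.sum()) if totals.sum() else float("nan"),
        "categories": categories,
    }
    return res, report


def mean_multiplicity(
    df: pd.DataFrame,
    arm: str | None = None,
    window: tuple[int, int] | None = None,
    categories: Iterable[str] | None = None,
) -> float:
    """Average diagnoses per consultation over selected records.

    ``window`` is an inclusive ``(first, last)`` range of ``month_index``.
    Raises on an empty selection or zero consultations in the window.
    """
    sel = df
    if arm is not None:
        sel = sel[sel["arm"] == arm]
    if window is not None:
        lo, hi = window
        sel = sel[(sel["month_index"] >= lo) & (sel["month_index"] <= hi)]
    if len(sel) == 0:
        raise ValueError("empty record selection")
    if categories is None:
        categories = category_columns(sel)
    total_diag = float(sel[list(categories)].to_numpy().sum())
    total_cons = float(sel["all_cause"].to_numpy().sum())
    if total_cons == 0:
        raise ValueError("zero consultations in window")
    return total_diag / total_cons
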