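"""Per-gate F1 concordance between automated and ground-truth gating.

Populations are compared event-wise over the identical event set:
TP/FP/FN counts feed F1 = 2TP / (2TP + FP + FN), the harmonic mean of
precision and recall.  Gates whose ground-truth population is smaller than
a cell-count threshold can be excluded from summaries, since F1 over a
handful of cells swings wildly with single-event differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["f1", "F1Report", "build_report", "summarize"]


def f1(mask_pred: np.ndarray, mask_truth: np.ndarray) -> tuple[int, int, int, float]:
    """Event-wise confusion counts and F1 between two boolean masks.

    When both masks are empty there is nothing to score; F1 is defined as
    1.0 (and logged as degenerate) — summaries normally exclude such gates
    through their cell-count threshold instead.
    """
    p = np.asarray(mask_pred, dtype=bool)
    t = np.asarray(mask_truth, dtype=bool)
    if p.shape != t.shape:
        raise InputError(f"mask length mismatch: {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    if tp == fp == fn == 0:
        logger.debug("both masks empty: degenerate F1 defined as 1.0")
        return 0, 0, 0, 1.0
    return tp, fp, fn, 2.0 * tp / (2.0 * tp + fp + fn)


@dataclass
class F1Report:
    """Rows of per-(sample, gate) confusion counts and F1."""

    rows: pd.DataFrame  # sample_id, gate_id, TP, FP, FN, F1, n_truth

    COLUMNS = ("sample_id", "gate_id", "TP", "FP", "FN", "F1", "n_truth")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise InputError(f"F1Report rows missing columns {sorted(missing)}")


def build_report(results, truths: dict[str, dict[str, np.ndarray]]) -> F1Report:
    """Score GatingResults against ground-truth per-gate masks.

    ``truths`` maps sample_id -> {gate_id -> boolean mask}.
    """
    rows = []
    for r in results if isinstance(results, (list, tuple)) else [results]:
        truth = truths[r.sample_id]
        for gate_id in r.gate_ids:
            if gate_id not in truth:
                continue
            tp, fp, fn, score = f1(r.masks[gate_id], truth[gate_id])
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "gate_id": gate_id,
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "F1": score,
                    "n_truth": tp + fn,
                }
            )
    return F1Report(pd.DataFrame(rows, columns=list(F1Report.COLUMNS)))


def summarize(report: F1Report, min_cells: int = 0):
    """Per-gate median / mean / SEM of F1 across samples, and overall median.

    Rows whose ground-truth population has fewer than ``min_cells`` events
    are excluded (and counted).  SEM uses the sample standard deviation
    (ddof=1); a single retained row has SEM 0.

    Returns (per_gate: DataFrame, overall_median: float, n_excluded: int).
    """
    rows = report.rows
    if rows.empty:
        raise InputError("cannot summarize an empty report")
    keep = rows[rows["n_truth"] >= min_cells]
    n_excluded = len(rows) - len(keep)
    if keep.empty:
        logger.warning("all %d rows excluded by min_cells=%d", len(rows), min_cells)
        return (
            pd.DataFrame(columns=["gate_id", "median", "mean", "sem", "n"]),
            float("nan"),
            n_excluded,
        )

    def _sem(x):
        return 0.0 if len(x) < 2 else float(np.std(x, ddof=1) / np.sqrt(len(x)))

    per_gate = (
        keep.groupby("gate_id")["F1"]
        .agg(median="median", mean="mean", sem=_sem, n="size")
        .reset_index()
    )
    overall_median = float(keep["F1"].median())
    return per_gate, overall_median, n_excluded
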