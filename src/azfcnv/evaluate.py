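"""Scoring of gr/gr calls against truth labels.

Beyond the standard sensitivity/specificity/FPR, this module also exposes the
precision-complement FP/(FP+TP) under the name ``fpr_called_positive``: published
benchmark tables for this kind of caller sometimes report "false positive
rate" computed against the *called-positive* denominator (e.g. 1 FP among 48
positive calls -> 0.021) rather than the conventional FP/(FP+TN).  Both are
computed so either convention can be reproduced; they are distinct fields and
never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .caller import CallResult, CallStatus
from .errors import ManifestMismatchError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    n_failed: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: float | None
    specificity: float | None
    fpr_standard: float | None
    fpr_called_positive: float | None


def confusion(
    truth: Mapping[str, int] | pd.DataFrame, calls: Sequence[CallResult]
) -> ConfusionMatrix:
    """Cross-tabulate calls against truth carrier labels.

    ``truth`` maps sample_id -> 1/0 (or is a DataFrame with ``sample_id`` and
    ``carrier`` columns).  Positive = GRGR_POSITIVE; every other completed
    status counts as a negative call.  CALL_FAILED samples are excluded from
    the matrix and counted separately.
    """
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["sample_id"], truth["carrier"]))
    call_ids = {c.sample_id for c in calls}
    if call_ids != set(truth):
        missing = sorted(set(truth) ^ call_ids)
        raise ManifestMismatchError(
            f"truth and calls cover different samples: {missing[:20]}"
        )
    tp = fp = tn = fn = failed = 0
    for c in calls:
        if c.status is CallStatus.CALL_FAILED:
            failed += 1
            continue
        called_pos = c.status is CallStatus.GRGR_POSITIVE
        true_pos = bool(truth[c.sample_id])
        if called_pos and true_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, tn, fn, n_failed=failed)


def metrics(m: ConfusionMatrix) -> PerformanceMetrics:
    """Sensitivity, specificity and both false-positive-rate conventions.

    Metrics with a zero denominator are reported as ``None``.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return PerformanceMetrics(
        sensitivity=ratio(m.tp, m.tp + m.fn),
        specificity=ratio(m.tn, m.tn + m.fp),
        fpr_standard=ratio(m.fp, m.fp + m.tn),
        fpr_called_positive=ratio(m.fp, m.fp + m.tp),
    )


def benchmark_report(
    results: Mapping[str, ConfusionMatrix]
) -> pd.DataFrame:
    """Benchmark-table-shaped report: one column per condition.

    Rows: confusion cells, then the derived metrics displayed to 3 decimals
    (full precision is available via :func:`metrics`).
    """
    rows = {}
    for label, m in results.items():
        pm = metrics(m)
        rows[label] = {
            "tp": m.tp,
            "fp": m.fp,
            "tn": m.tn,
            "fn": m.fn,
            "n_failed": m.n_failed,
            "sensitivity": None if pm.sensitivity is None else round(pm.sensitivity, 3),
            "specificity": None if pm.specificity is None else round(pm.specificity, 3),
            "fpr_standard": None
            if pm.fpr_standard is None
            else round(pm.fpr_standard, 3),
            "fpr_called_positive": None if pm.fpr_called_positive is None else round(pm.fpr_called_positive, 3),
        }
    return pd.DataFrame(rows)
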