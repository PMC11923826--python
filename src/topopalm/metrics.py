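"""Classifier evaluation: PR/ROC curves, threshold metrics, site ranking.

Definitions used throughout (and relied on by the tests' brute-force
confusion-matrix oracle):

* A site is called positive at threshold t when its score is ≥ t.
* The precision–recall curve sweeps the unique score values in
  descending order (ties grouped); its AUC is the trapezoid over the
  (recall, precision) points with a (0, 1) anchor prepended.
* F1 = 2PR/(P+R); MCC is the standard confusion-matrix formula.  Ratios
  with zero denominators are defined as 0 so degenerate predictors
  (constant scores, empty calls) yield 0 rather than NaN.
* Threshold counts ("how many sites above the high cutoff") use strict
  inequality, score > t.
* Ranks are ordinal, 1 = highest score; ties broken by accession then
  position, so ranks are always a permutation of 1..N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "DEFAULT_THRESHOLDS",
    "confusion_at",
    "threshold_metrics",
    "pr_curve",
    "pr_auc",
    "MetricReport",
    "evaluate",
    "rank_and_threshold",
    "ingest_external_scores",
]

DEFAULT_THRESHOLDS: Tuple[float, ...] = (0.25, 0.50, 0.75)


def confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> Tuple[int, int, int, int]:
    """(TP, FP, FN, TN) calling positive at score ≥ threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    return tp, fp, fn, tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def threshold_metrics(tp: int, fp: int, fn: int, tn: int) -> Dict[str, float]:
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Precision/recall at every unique score threshold (descending)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    for t in np.unique(scores)[::-1]:
        tp, fp, fn, tn = confusion_at(scores, labels, t)
        m = threshold_metrics(tp, fp, fn, tn)
        rows.append(
            {"threshold": t, "precision": m["precision"], "recall": m["recall"]}
        )
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall"])


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the precision–recall sweep.

    The sweep points (recall ascending) are prefixed with the (0, 1)
    anchor so that a perfect separator scores exactly 1.
    """
    curve = pr_curve(scores, labels)
    recall = np.concatenate([[0.0], curve["recall"].to_numpy()])
    precision = np.concatenate([[1.0], curve["precision"].to_numpy()])
    order = np.argsort(recall, kind="stable")
    return float(np.trapezoid(precision[order], recall[order]))


@dataclass
class MetricReport:
    """Evaluation bundle: global AUCs plus metrics at named thresholds."""

    roc_auc: float
    pr_auc: float
    at_thresholds: pd.DataFrame  # threshold, tp..tn, precision..mcc
    threshold_curve: pd.DataFrame  # fine grid: threshold, precision..mcc
    pr_points: pd.DataFrame
    n_sites: int
    n_positive: int

    def summary(self) -> str:
        lines = [
            f"sites: {self.n_sites}  positives: {self.n_positive}",
            f"ROC AUC: {self.roc_auc:.4f}   PR AUC: {self.pr_auc:.4f}",
            "",
            self.at_thresholds.to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    grid_points: int = 101,
) -> MetricReport:
    """Full metric report for aligned score/label vectors.

    Raises when the labels contain a single class: every reported metric
    is undefined or degenerate without both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes in the labels")

    def _rows(ts) -> pd.DataFrame:
        rows = []
        for t in ts:
            tp, fp, fn, tn = confusion_at(scores, labels, t)
            rows.append(
                {
                    "threshold": float(t),
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "tn": tn,
                    **threshold_metrics(tp, fp, fn, tn),
                }
            )
        return pd.DataFrame(rows)

    grid = np.linspace(0.0, 1.0, grid_points)
    return MetricReport(
        roc_auc=float(roc_auc_score(labels, scores)),
        pr_auc=pr_auc(scores, labels),
        at_thresholds=_rows(thresholds),
        threshold_curve=_rows(grid),
        pr_points=pr_curve(scores, labels),
        n_sites=int(len(labels)),
        n_positive=int(labels.sum()),
    )


def rank_and_threshold(
    scored_sites: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    known_sites: Set[Tuple[str, int]] | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Rank scored sites and tally threshold bands and novelty.

    ``scored_sites`` needs accession, position and score columns.
    Returns (rank table, threshold summary).  The rank table adds
    ``rank`` (ordinal, 1 = best, ties by accession then position),
    ``known`` and ``novel`` (above the highest threshold and not known).
    The summary has one row per threshold with the strict-``>`` count,
    plus known/novel tallies at the highest threshold.
    """
    known_sites = known_sites or set()
    table = scored_sites.copy()
    table = table.sort_values(
        ["score", "accession", "position"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    keys = list(zip(table["accession"], table["position"]))
    table["known"] = [k in known_sites for k in keys]
    high = max(thresholds)
    table["novel"] = (table["score"] > high) & ~table["known"]

    rows = []
    for t in sorted(thresholds):
        above = int((table["score"] > t).sum())
        row = {"threshold": t, "n_above": above}
        if t == high:
            row["n_known_above"] = int(
                (table["known"] & (table["score"] > t)).sum()
            )
            row["n_novel_above"] = above - row["n_known_above"]
        rows.append(row)
    return table, pd.DataFrame(rows)


def ingest_external_scores(
    external: pd.DataFrame,
    labeled_sites: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> Tuple[MetricReport, pd.DataFrame]:
    """Evaluate another tool's per-site scores on the same labels.

    ``external`` needs accession, position, score; ``labeled_sites``
    needs accession, position, label.  Metrics are computed over the
    intersection so comparisons are apples-to-apples; unmatched rows are
    returned for logging, not silently dropped.
    """
    for frame, cols in (
        (external, {"accession", "position", "score"}),
        (labeled_sites, {"accession", "position", "label"}),
    ):
        if not cols.issubset(frame.columns):
            raise ValueError(f"table lacks required columns {sorted(cols)}")
    joined = labeled_sites[["accession", "position", "label"]].merge(
        external[["accession", "position", "score"]],
        on=["accession", "position"],
        how="left",
    )
    unmatched = joined.loc[joined["score"].isna(), ["accession", "position"]]
    matched = joined.dropna(subset=["score"])
    report = evaluate(
        matched["score"].to_numpy(),
        matched["label"].to_numpy(),
        thresholds,
    )
    return report, unmatched.reset_index(drop=True)
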