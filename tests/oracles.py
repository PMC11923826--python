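"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available —
explicit scans and counting loops — deliberately sharing no code with the
implementation paths it checks.
"""

from __future__ import annotations

import math
import re
from typing import List, Optional, Sequence, Tuple

from topopalm.topology import ProteinRecord, SegmentKind, TMOrientation


def brute_digest(sequence: str) -> List[str]:
    """Regex-scan trypsin digest: cleave after K/R not followed by P."""
    out, start = [], 0
    for m in re.finditer(r"[KR](?!P)", sequence):
        out.append(sequence[start : m.end()])
        start = m.end()
    if start < len(sequence):
        out.append(sequence[start:])
    return out


def brute_confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> Tuple[int, int, int, int]:
    """Explicit-loop confusion matrix at ``score >= threshold``."""
    tp = fp = fn = tn = 0
    for s, y in zip(scores, labels):
        if s >= threshold:
            if y == 1:
                tp += 1
            else:
                fp += 1
        else:
            if y == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def brute_threshold_metrics(
    tp: int, fp: int, fn: int, tn: int
) -> Tuple[float, float, float, float]:
    """(precision, recall, f1, mcc) with 0-for-0/0 conventions."""
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return precision, recall, f1, mcc


def brute_pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal PR AUC from loop-enumerated unique-score thresholds,
    with the (recall 0, precision 1) anchor."""
    points = [(0.0, 1.0)]
    for t in sorted(set(scores), reverse=True):
        tp, fp, fn, tn = brute_confusion(scores, labels, t)
        precision, recall, _, _ = brute_threshold_metrics(tp, fp, fn, tn)
        points.append((recall, precision))
    points.sort(key=lambda p: p[0])
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points[:-1], points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def scan_interface_oracle(
    protein: ProteinRecord, position: int
) -> Optional[int]:
    """Walk outward residue by residue to the membrane interface.

    Inside a TM, walk toward the cytoplasmic end (C-terminal for inward,
    N-terminal for outward) counting steps until the next step would
    leave the helix.  In a soluble segment, walk in each direction until
    the segment kind changes; a direction contributes a candidate only
    when it exits directly into a transmembrane segment.  Returns None
    when no direction reaches a TM (unknown orientation included).
    """

    def seg_at(q: int):
        for s in protein.segments:
            if s.start <= q <= s.end:
                return s
        return None

    seg = seg_at(position)
    assert seg is not None
    if seg.kind is SegmentKind.TRANSMEMBRANE:
        if seg.orientation is TMOrientation.INWARD:
            step = 1
        elif seg.orientation is TMOrientation.OUTWARD:
            step = -1
        else:
            return None
        d, q = 0, position
        while True:
            nxt = q + step
            if nxt < seg.start or nxt > seg.end:
                return d
            q, d = nxt, d + 1
    candidates = []
    for step in (-1, 1):
        d, q = 0, position
        while True:
            nxt = q + step
            if nxt < 1 or nxt > len(protein.sequence):
                break
            nxt_seg = seg_at(nxt)
            if nxt_seg is not seg:
                if (
                    nxt_seg is not None
                    and nxt_seg.kind is SegmentKind.TRANSMEMBRANE
                ):
                    candidates.append(d)
                break
            q, d = nxt, d + 1
    return min(candidates) if candidates else None
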