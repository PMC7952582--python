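"""Object-level scoring of predicted against true segmentations.

Predicted and truth label maps are compared by intersection-over-union:
candidate (truth, prediction) pairs are matched greedily in descending
IoU (ties broken by ascending ids), one-to-one, keeping only pairs at or
above the IoU threshold.  Unmatched truths are false negatives, unmatched
predictions false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MatchedPair", "MatchReport", "match_objects"]


@dataclass(frozen=True)
class MatchedPair:
    truth_id: int
    predicted_label: int
    iou: float
    relative_area_error: float  # |pred - truth| / truth


@dataclass
class MatchReport:
    """Matching outcome for one scene.

    When there are no predictions, precision is reported as 1.0 by
    convention (no prediction is wrong) and ``zero_predictions`` is set so
    consumers can tell the degenerate case apart.
    """

    matches: list[MatchedPair] = field(default_factory=list)
    n_truth: int = 0
    n_predicted: int = 0
    precision: float = 1.0
    recall: float = 1.0
    zero_predictions: bool = False
    iou_min: float = 0.5

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    def median_relative_area_error(self) -> float:
        if not self.matches:
            return float("nan")
        return float(np.median([m.relative_area_error for m in self.matches]))

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_predicted": self.n_predicted,
            "n_matched": self.n_matched,
            "precision": self.precision,
            "recall": self.recall,
            "zero_predictions": self.zero_predictions,
            "iou_min": self.iou_min,
            "matches": [
                {
                    "truth_id": m.truth_id,
                    "predicted_label": m.predicted_label,
                    "iou": m.iou,
                    "relative_area_error": m.relative_area_error,
                }
                for m in self.matches
            ],
        }


def match_objects(
    truth: np.ndarray, predicted: np.ndarray, iou_min: float = 0.5
) -> MatchReport:
    """Greedy one-to-one IoU matching between two label maps."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs predicted {p.shape}")
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must lie in (0, 1]")

    t_ids = np.unique(t[t > 0])
    p_ids = np.unique(p[p > 0])
    report = MatchReport(
        n_truth=int(t_ids.size),
        n_predicted=int(p_ids.size),
        iou_min=iou_min,
        zero_predictions=p_ids.size == 0,
    )
    if t_ids.size == 0 or p_ids.size == 0:
        report.recall = 1.0 if t_ids.size == 0 else 0.0
        report.precision = 1.0  # convention for zero predictions
        return report

    t_area = {int(i): int(n) for i, n in zip(*np.unique(t[t > 0], return_counts=True))}
    p_area = {int(i): int(n) for i, n in zip(*np.unique(p[p > 0], return_counts=True))}

    # joint counts over pixels where both maps are foreground
    both = (t > 0) & (p > 0)
    if both.any():
        pmax = int(p_ids.max()) + 1
        pair_codes = t[both].astype(np.int64) * pmax + p[both].astype(np.int64)
        codes, inter = np.unique(pair_codes, return_counts=True)
        candidates = []
        for code, n_int in zip(codes, inter):
            ti, pi = int(code // pmax), int(code % pmax)
            iou = n_int / (t_area[ti] + p_area[pi] - n_int)
            if iou >= iou_min:
                candidates.append((float(iou), ti, pi))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        used_t: set[int] = set()
        used_p: set[int] = set()
        for iou, ti, pi in candidates:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            report.matches.append(
                MatchedPair(
                    truth_id=ti,
                    predicted_label=pi,
                    iou=iou,
                    relative_area_error=abs(p_area[pi] - t_area[ti]) / t_area[ti],
                )
            )
    report.recall = report.n_matched / report.n_truth
    report.precision = report.n_matched / report.n_predicted
    return report
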