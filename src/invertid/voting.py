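"""Specimen-level aggregation of per-image classifications.

A specimen is photographed many times from two orthogonal angles while it
tumbles, so individual frames can be misclassified even when most are not.
Two aggregation schemes turn per-frame outputs into one specimen label:

* **majority vote** — each frame casts one equal-weight vote for its argmax
  class; the specimen takes the class with the most votes. Vote ties break
  by the larger summed score among the tied classes, then by lowest index.
* **max scoring sum** — the raw unbounded score vectors of all frames are
  summed element-wise and the specimen takes the argmax of the total. Frames
  the model finds ambiguous contribute small scores everywhere, so this
  weighting accounts for per-frame uncertainty.

Both schemes reduce to the per-image prediction for single-frame specimens,
are invariant to frame order, and return the unanimous class when all frames
agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpecimenPrediction", "majority_vote", "score_sum_vote"]


def _score_stack(per_image_scores) -> np.ndarray:
    scores = np.asarray(per_image_scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score vectors must share a common length")
    return scores


def majority_vote(per_image_classes, per_image_scores=None) -> int:
    """Equal-weight vote over per-frame predicted classes.

    Ties in vote count are broken by the larger summed score over the tied
    classes (when scores are given), then deterministically by lowest class
    index.
    """
    classes = np.asarray(per_image_classes, dtype=int)
    if classes.size == 0:
        raise ValueError("at least one per-image class required")
    counts = np.bincount(classes)
    top = np.flatnonzero(counts == counts.max())
    if len(top) == 1 or per_image_scores is None:
        return int(top[0])
    sums = _score_stack(per_image_scores).sum(axis=0)
    tied_sums = sums[top]
    return int(top[np.argmax(tied_sums)])  # argmax keeps lowest index on ties


def score_sum_vote(per_image_scores) -> int:
    """Argmax of the element-wise sum of per-frame score vectors."""
    scores = _score_stack(per_image_scores)
    if scores.shape[0] == 0:
        raise ValueError("at least one score vector required")
    return int(np.argmax(scores.sum(axis=0)))


@dataclass
class SpecimenPrediction:
    """Per-frame outputs and the aggregated decisions for one specimen."""

    specimen_id: str
    per_image_classes: list
    per_image_scores: np.ndarray
    voted_class_majority: int
    voted_class_scoresum: int

    @classmethod
    def from_scores(cls, specimen_id: str, scores: np.ndarray) -> "SpecimenPrediction":
        scores = _score_stack(scores)
        classes = [int(np.argmax(s)) for s in scores]
        return cls(
            specimen_id,
            classes,
            scores,
            majority_vote(classes, scores),
            score_sum_vote(scores),
        )
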