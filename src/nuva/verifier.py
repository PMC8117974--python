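"""Posteriorgram matching: local distance, DTW, and the threshold decision.

Given a healthy-speaker template H = (p_h1 ... p_hn) and an attempt
A = (p_a1 ... p_am), the local distance between frames is the negative log
inner product phi(i, j) = -log(p_hi . p_aj), floored so it stays finite.
Dynamic time warping finds the monotone path from (1, 1) to (n, m) with
minimum accumulated distance using the symmetric step set
{(1,0), (0,1), (1,1)}.  The decision statistic is the accumulated cost
divided by the path length (so thresholds live on the per-frame scale), an
attempt is scored against every available template for the target word, the
minimum is taken, and the attempt is "correct" iff that minimum is strictly
below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .posteriorgram import Posteriorgram

__all__ = [
    "LOG_FLOOR",
    "local_distance",
    "distance_matrix",
    "DtwResult",
    "dtw",
    "Verdict",
    "verify",
    "combination_auc",
]

LOG_FLOOR = 1e-10

_STEPS = ((1, 0), (0, 1), (1, 1))


def local_distance(p_h: np.ndarray, p_a: np.ndarray, floor: float = LOG_FLOOR) -> float:
    """-log of the inner product of two posterior rows, floored at `floor`."""
    p_h = np.asarray(p_h, dtype=np.float64)
    p_a = np.asarray(p_a, dtype=np.float64)
    if p_h.shape != p_a.shape:
        raise ValueError(f"row length mismatch: {p_h.shape} vs {p_a.shape}")
    return float(-np.log(max(float(p_h @ p_a), floor)))


def distance_matrix(healthy: Posteriorgram, attempt: Posteriorgram,
                    floor: float = LOG_FLOOR) -> np.ndarray:
    """n x m matrix of phi(i, j) = -log(p_hi . p_aj)."""
    if healthy.inventory != attempt.inventory:
        raise ValueError("posteriorgrams use different phone inventories")
    inner = healthy.probs @ attempt.probs.T
    return -np.log(np.maximum(inner, floor))


@dataclass(frozen=True)
class DtwResult:
    """Minimum-cost monotone alignment of two sequences."""

    accumulated: float
    path: tuple
    normalized: float

    @property
    def path_length(self) -> int:
        return len(self.path)


def _dtw_matrix(local: np.ndarray) -> np.ndarray:
    n, m = local.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = local[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + local[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + local[i, 0]
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = local[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    return acc


def _backtrack(acc: np.ndarray) -> tuple:
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            choices = ((acc[i - 1, j - 1], i - 1, j - 1),
                       (acc[i - 1, j], i - 1, j),
                       (acc[i, j - 1], i, j - 1))
            _, i, j = min(choices, key=lambda c: c[0])
        path.append((i, j))
    return tuple(reversed(path))


def dtw(healthy: Posteriorgram, attempt: Posteriorgram,
        floor: float = LOG_FLOOR) -> DtwResult:
    """Globally optimal DTW alignment of template and attempt.

    Returns the accumulated cost, one minimizing path, and the
    length-normalized cost used as the decision statistic.
    """
    local = distance_matrix(healthy, attempt, floor)
    acc = _dtw_matrix(local)
    path = _backtrack(acc)
    accumulated = float(acc[-1, -1])
    return DtwResult(accumulated, path, accumulated / len(path))


@dataclass(frozen=True)
class Verdict:
    """Outcome of verifying one attempt against a word's templates."""

    word: str
    per_template: tuple
    min_distance: float
    threshold: float
    decision: str  # "correct" | "incorrect"

    @property
    def correct(self) -> bool:
        return self.decision == "correct"

    def to_dict(self) -> dict:
        return {
            "word": self.word,
            "per_template": list(self.per_template),
            "min_distance": self.min_distance,
            "threshold": self.threshold,
            "decision": self.decision,
        }


def verify(attempt: Posteriorgram, templates, threshold: float,
           word: str = "", floor: float = LOG_FLOOR) -> Verdict:
    """Score an attempt against every template; decide on the minimum.

    Ties at the threshold are incorrect (the comparison is strict).
    """
    templates = list(templates)
    if not templates:
        raise ValueError(f"no templates available for word {word!r}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    per_template = tuple(dtw(t, attempt, floor).normalized for t in templates)
    min_distance = min(per_template)
    decision = "correct" if min_distance < threshold else "incorrect"
    return Verdict(word, per_template, min_distance, threshold, decision)


def combination_auc(per_template_distances: np.ndarray, labels) -> dict:
    """ROC AUC of each template-combination criterion.

    Rows are attempts, columns per-template normalized distances; labels are
    1 for truly correct attempts.  Criteria: the first template alone, and
    the minimum, maximum, and mean over templates.  Smaller distance means
    more likely correct, so the score fed to the ROC is the negated
    combined distance.
    """
    d = np.asarray(per_template_distances, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need a 2-D distance matrix with >= 2 templates")
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present to compute AUC")
    combined = {
        "first": d[:, 0],
        "min": d.min(axis=1),
        "max": d.max(axis=1),
        "mean": d.mean(axis=1),
    }
    return {name: float(roc_auc_score(y, -dist)) for name, dist in combined.items()}
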