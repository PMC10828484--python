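"""One-to-one point matching for scoring detections against plants."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def match_points(detected: np.ndarray, planted: np.ndarray,
                 max_dist: float) -> list:
    """Optimal (Hungarian) one-to-one assignment between two point sets.

    Returns a list of (detected index, planted index) pairs whose
    Euclidean distance is at most ``max_dist``; each point is used once.
    """
    a = np.asarray(detected, dtype=float)
    b = np.asarray(planted, dtype=float)
    if a.size == 0 or b.size == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    cost = np.where(d <= max_dist, d, 1e6)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= max_dist]


def detection_scores(detected: np.ndarray, planted: np.ndarray,
                     max_dist: float) -> tuple:
    """(sensitivity, false-discovery rate) of a detection against plants."""
    pairs = match_points(detected, planted, max_dist)
    tp = len(pairs)
    sens = tp / len(planted) if len(planted) else float("nan")
    fdr = (len(detected) - tp) / len(detected) if len(detected) else 0.0
    return sens, fdr
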