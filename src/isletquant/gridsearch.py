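"""Annotation-guided parameter selection.

The segmentation stages were tuned in the original workflow by exhaustive
search: every combination of a small parameter grid is run on a handful of
testing images, each output is scored against a manual annotation, and the
best-scoring combination is adopted.  Two scoring tasks exist:

* **mask** — candidate islet masks against manually drawn masks, scored by
  Jaccard similarity (Dice available; the two rank identically);
* **nuclei** — detected nucleus centroids against manually clicked ones,
  scored by the detection-count error and the mean nearest-neighbor
  distance from each manual centroid to the closest detection.

Scores are averaged over the testing images before ranking. Ranking is
deterministic: mask task maximizes mean Jaccard; nuclei task minimizes
(count_error, mean_nn_distance) lexicographically — count first; remaining
ties go to grid order, so the procedure is auditable and reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class GridSpec:
    """Named ordered axes; the grid is their Cartesian product."""

    axes: tuple  # tuple of (name, tuple(values)) preserving declaration order

    @classmethod
    def from_dict(cls, axes: dict) -> "GridSpec":
        return cls(axes=tuple((k, tuple(v)) for k, v in axes.items()))

    @property
    def size(self) -> int:
        out = 1
        for _, vals in self.axes:
            out *= len(vals)
        return out


@dataclass(frozen=True)
class CandidateScore:
    """One parameter combination with its (aggregated) similarity metrics.

    Exactly one metric group is populated: ``mask_jaccard`` for mask
    tasks, ``(count_error, mean_nn_distance_px)`` for nuclei tasks.
    """

    combo: dict
    grid_index: int
    mask_jaccard: float | None = None
    count_error: float | None = None
    mean_nn_distance_px: float | None = None

    def __post_init__(self):
        mask_side = self.mask_jaccard is not None
        nuc_side = self.count_error is not None or self.mean_nn_distance_px is not None
        if mask_side == nuc_side:
            raise ValueError("exactly one metric group must be populated")


def expand_grid(spec: GridSpec) -> list[dict]:
    """All combinations in lexicographic order over the declared axes."""
    names = [k for k, _ in spec.axes]
    value_lists = [list(v) for _, v in spec.axes]
    if any(len(v) == 0 for v in value_lists):
        raise ValueError("every axis must be non-empty")
    return [dict(zip(names, combo)) for combo in itertools.product(*value_lists)]


def mask_similarity(candidate: np.ndarray, manual: np.ndarray, metric: str = "jaccard") -> float:
    """Jaccard (default) or Dice similarity of two binary masks.

    Two empty masks are in perfect agreement (similarity 1).
    """
    a = np.asarray(candidate, dtype=bool)
    b = np.asarray(manual, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = np.count_nonzero(a & b)
    if metric == "jaccard":
        union = np.count_nonzero(a | b)
        return 1.0 if union == 0 else inter / union
    if metric == "dice":
        tot = np.count_nonzero(a) + np.count_nonzero(b)
        return 1.0 if tot == 0 else 2 * inter / tot
    raise ValueError(f"unknown metric {metric!r}")


def nuclei_agreement(auto_centroids: np.ndarray, manual_centroids: np.ndarray) -> tuple[int, float]:
    """Count error and mean manual→nearest-auto distance.

    count_error = |n_auto − n_manual|; mean_nn_distance is the mean over
    manual centroids of the Euclidean distance to the nearest detection
    (infinite when there are manual centroids but no detections; 0 when
    there are no manual centroids).
    """
    auto = np.asarray(auto_centroids, dtype=float).reshape(-1, 2)
    manual = np.asarray(manual_centroids, dtype=float).reshape(-1, 2)
    count_error = abs(len(auto) - len(manual))
    if len(manual) == 0:
        return count_error, 0.0
    if len(auto) == 0:
        return count_error, float("inf")
    d, _ = cKDTree(auto).query(manual)
    return count_error, float(np.mean(d))


def select_optimum(scores: list[CandidateScore], task: str) -> CandidateScore:
    """Deterministic replacement of the original workflow's manual sense-check.

    mask task: maximize mask_jaccard; nuclei task: minimize
    (count_error, mean_nn_distance) lexicographically; residual ties go to
    the earlier grid-order combination.
    """
    if not scores:
        raise ValueError("no candidates to rank")
    return ranked(scores, task)[0]


def ranked(scores: list[CandidateScore], task: str) -> list[CandidateScore]:
    """Candidates sorted best-first by the task's deterministic rule."""
    if task == "mask":
        if any(s.mask_jaccard is None for s in scores):
            raise ValueError("mask task requires mask_jaccard on every candidate")
        key = lambda s: (-s.mask_jaccard, s.grid_index)
    elif task == "nuclei":
        if any(s.count_error is None for s in scores):
            raise ValueError("nuclei task requires nuclei metrics on every candidate")
        key = lambda s: (s.count_error, s.mean_nn_distance_px, s.grid_index)
    else:
        raise ValueError(f"unknown task {task!r}")
    return sorted(scores, key=key)


def scores_to_frame(scores: list[CandidateScore]) -> pd.DataFrame:
    """Flatten candidate scores to a table (one row per combo)."""
    rows = []
    for s in scores:
        row = {"grid_index": s.grid_index, **s.combo}
        if s.mask_jaccard is not None:
            row["mask_jaccard"] = s.mask_jaccard
        if s.count_error is not None:
            row["count_error"] = s.count_error
            row["mean_nn_distance_px"] = s.mean_nn_distance_px
        rows.append(row)
    return pd.DataFrame(rows)
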