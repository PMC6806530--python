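"""Leaf extraction by region growing with a smoothness constraint.

Seeds are processed in order of increasing curvature.  A neighbor joins a
region when the angle between its normal and the normal of the point it
was reached from stays below the smoothness threshold; it seeds further
growth only while its own curvature stays below the curvature threshold.
Regions that stay too small, and points with invalid normals, are
rejected as noise.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phytoprobe.geometry import CURVATURE_MAX, NormalField, knn

__all__ = ["SegmentationParams", "Segmentation", "region_grow",
           "segmentation_quality"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs controlling leaf-segment granularity.

    theta_smooth_deg : max angle between a candidate's normal and the
        normal of the region point it is reached from.
    c_max : curvature threshold above which a joined point stops seeding
        further growth.
    min_size : minimum points per kept segment.
    k : neighborhood size (must match the normal field's ``k``).
    """

    theta_smooth_deg: float = 10.0
    c_max: float = 0.05
    min_size: int = 100
    k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_smooth_deg < 90.0:
            raise ValueError("theta_smooth must be in (0, 90) degrees")
        if not 0.0 <= self.c_max <= CURVATURE_MAX + 1e-12:
            raise ValueError("c_max must be in [0, 1/3]")
        if self.min_size < 3:
            raise ValueError("min_size must be >= 3")


@dataclass(frozen=True)
class Segmentation:
    """Disjoint leaf segments plus a rejected-noise set covering the cloud."""

    segments: tuple[np.ndarray, ...]
    noise: np.ndarray
    params: SegmentationParams | None = field(default=None, compare=False)

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.segments) + len(self.noise)

    def labels(self, n: int | None = None) -> np.ndarray:
        """Per-point segment ids, 1-based; 0 marks noise."""
        n = self.n_points if n is None else n
        lab = np.zeros(n, dtype=int)
        for sid, seg in enumerate(self.segments, start=1):
            lab[seg] = sid
        return lab

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "schema_version": 1,
            "segments": [seg.tolist() for seg in self.segments],
            "noise": self.noise.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @staticmethod
    def from_json(path) -> "Segmentation":
        payload = json.loads(Path(path).read_text())
        return Segmentation(
            segments=tuple(np.asarray(s, dtype=int)
                           for s in payload["segments"]),
            noise=np.asarray(payload["noise"], dtype=int),
        )


def region_grow(cloud, field: NormalField,
                params: SegmentationParams | None = None) -> Segmentation:
    """Smoothness-constrained region growing over a point cloud.

    Deterministic: seeds are taken in ascending-curvature order with index
    tie-breaking, and neighbor expansion follows the fixed k-NN ordering.
    """
    params = params or SegmentationParams()
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    n = len(pts)
    if len(field) != n:
        raise ValueError(
            f"normal field size {len(field)} != cloud size {n}")

    nbrs = knn(pts, min(params.k, n))
    cos_thresh = np.cos(np.radians(params.theta_smooth_deg))
    assigned = np.zeros(n, dtype=bool)
    assigned[~field.valid] = True          # invalid normals go to noise
    # Ascending curvature, index ties -> deterministic seed order.
    seed_order = np.lexsort((np.arange(n), field.curvatures))

    segments: list[np.ndarray] = []
    noise_parts: list[np.ndarray] = [np.flatnonzero(~field.valid)]

    for seed in seed_order:
        if assigned[seed]:
            continue
        region = [seed]
        assigned[seed] = True
        queue = deque([seed])
        while queue:
            cur = queue.popleft()
            cur_normal = field.normals[cur]
            for nb in nbrs[cur]:
                if assigned[nb]:
                    continue
                cosang = abs(float(cur_normal @ field.normals[nb]))
                if cosang + 1e-12 < cos_thresh:
                    continue
                assigned[nb] = True
                region.append(nb)
                if field.curvatures[nb] <= params.c_max:
                    queue.append(nb)
        region_arr = np.array(sorted(region), dtype=int)
        if len(region_arr) >= params.min_size:
            segments.append(region_arr)
        else:
            noise_parts.append(region_arr)

    noise = np.sort(np.concatenate(noise_parts)) if noise_parts \
        else np.empty(0, dtype=int)
    # Largest segments first; size ties by smallest member index.
    segments.sort(key=lambda s: (-len(s), s[0] if len(s) else 0))
    return Segmentation(segments=tuple(segments), noise=noise, params=params)


def segmentation_quality(pred: Segmentation, truth) -> dict:
    """Point-level precision/recall of leaf-vs-noise plus per-leaf splits.

    ``truth`` is a labeled cloud (label 0 = non-leaf).  Precision and
    recall treat "in any predicted segment" as positive.  For each true
    leaf, the per-leaf count is the number of predicted segments whose
    majority true label is that leaf.
    """
    true_labels = np.asarray(getattr(truth, "labels", truth), dtype=int)
    n = len(true_labels)
    pred_leaf = np.zeros(n, dtype=bool)
    for seg in pred.segments:
        pred_leaf[seg] = True
    true_leaf = true_labels > 0

    tp = int(np.sum(pred_leaf & true_leaf))
    precision = tp / pred_leaf.sum() if pred_leaf.any() else 0.0
    recall = tp / true_leaf.sum() if true_leaf.any() else 0.0

    per_leaf: dict[int, int] = {
        int(lid): 0 for lid in np.unique(true_labels[true_labels > 0])}
    for seg in pred.segments:
        labs, counts = np.unique(true_labels[seg], return_counts=True)
        majority = int(labs[np.argmax(counts)])
        if majority > 0:
            per_leaf[majority] = per_leaf.get(majority, 0) + 1
    return {
        "precision": float(precision),
        "recall": float(recall),
        "segments_per_leaf": per_leaf,
    }
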