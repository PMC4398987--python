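"""Detection scoring against spatiotemporal ground truth.

Evaluation is at the level of *detection*, not segmentation quality: a
per-frame detection mask scores a hit when it spatially coincides with a
labeled ground-truth region. Counting is per frame-level region instance,
aggregated over the sequence. A ground-truth region hit by several
detections counts once; a detection that coincides with no region is a
false detection.

    detection rate      = |GT regions hit| / |GT regions|
    false-positive rate = |false detections| / |detections|
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruth",
    "MatchResult",
    "match_detections",
    "detection_rate",
    "false_positive_rate",
]


@dataclass
class GroundTruth:
    """Per-frame labeled region masks.

    ``labels[t]`` is an integer image, 0 = background, region ids > 0
    unique within the frame. Overlapping animals form one region.
    ``occluded[t]`` lists region ids that are fully hidden in frame t but
    known to be present (the ground truth stays continuous through
    occlusions).
    """

    labels: dict[int, np.ndarray]
    occluded: dict[int, set[int]] = field(default_factory=dict)

    def regions(self, t: int) -> list[int]:
        lab = self.labels[t]
        ids = np.unique(lab)
        return [int(i) for i in ids if i != 0]

    @property
    def n_regions(self) -> int:
        """Total number of frame-level region instances."""
        return sum(len(self.regions(t)) for t in self.labels)


@dataclass
class MatchResult:
    hits: set[tuple[int, int]]  # (frame, region id)
    false_detections: list[tuple[int, int]]  # (frame, detection index)
    n_detections: int


def match_detections(
    detections: dict[int, list[np.ndarray]],
    gt: GroundTruth,
    min_overlap: float = 0.0,
    mixed_policy: str = "hit",
) -> MatchResult:
    """Match per-frame detection masks against ground-truth regions.

    A detection hits a region iff ``|detection ∩ region| / |detection|``
    is at least ``min_overlap`` (any positive overlap when
    ``min_overlap=0``). Detections hitting no region are false detections.
    ``mixed_policy`` controls detections that coincide with a region but
    lie mostly on background: ``"hit"`` (default) counts them as hits,
    ``"false"`` additionally counts them as false when more than half of
    their area is background.
    """
    if not 0 <= min_overlap <= 1:
        raise ValueError("min_overlap must be in [0, 1]")
    if mixed_policy not in ("hit", "false"):
        raise ValueError(f"unknown mixed_policy {mixed_policy!r}")
    hits: set[tuple[int, int]] = set()
    false_detections: list[tuple[int, int]] = []
    n_det = 0
    for t, masks in detections.items():
        if t not in gt.labels:
            continue
        lab = gt.labels[t]
        for i, mask in enumerate(masks):
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != lab.shape:
                raise ValueError("detection and ground truth grids differ")
            area = int(mask.sum())
            if area == 0:
                continue
            n_det += 1
            covered = lab[mask]
            ids, counts = np.unique(covered[covered > 0], return_counts=True)
            hit_any = False
            for rid, cnt in zip(ids, counts):
                ov = cnt / area
                if (min_overlap == 0 and ov > 0) or (min_overlap > 0 and ov >= min_overlap):
                    hits.add((t, int(rid)))
                    hit_any = True
            if not hit_any:
                false_detections.append((t, i))
            elif mixed_policy == "false" and (covered == 0).sum() / area > 0.5:
                false_detections.append((t, i))
    return MatchResult(hits=hits, false_detections=false_detections, n_detections=n_det)


def detection_rate(result: MatchResult, gt: GroundTruth) -> float:
    """Fraction of ground-truth region instances hit by a detection."""
    total = gt.n_regions
    if total == 0:
        raise ValueError("ground truth contains no regions")
    return len(result.hits) / total


def false_positive_rate(result: MatchResult) -> float:
    """Fraction of detections that are false; 0 when there are none."""
    if result.n_detections == 0:
        return 0.0
    return len(result.false_detections) / result.n_detections
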