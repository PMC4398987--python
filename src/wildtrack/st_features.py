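"""Spatiotemporal validation features of a track.

A track that really follows an animal behaves differently from a false
detection: it can be traced for a long time with few gaps, its area changes
smoothly, and — since elephant skin is poorly textured — its interior shows
few edges and a stable texture over time. Five scalar features capture
this:

- ``duration`` — lifetime of the track in frames,
- ``instability`` — fraction of lifetime frames in which the detection
  could not be tracked (gap fraction),
- ``shape_change`` — ``(max(a) − min(a)) / max(a)`` over the per-frame
  areas ``a_1..a_n`` (0 for a constant area),
- ``edge_density`` — mean over frames of the summed 5-bin edge histogram,
  i.e. the mean fraction of the track's blocks that are edge blocks,
- ``texture_variation`` — mean over the 5 bins of each bin's value range
  (max − min) across frames.

The per-frame texture summary is a 5-bin oriented edge histogram in the
MPEG-7 style: the mask is tiled into 2×2 pixel blocks, each fully covered
block is scored by five 2×2 edge filters (horizontal, vertical, two
diagonals, non-directional), and a block counts as an edge block of its
strongest filter iff that response reaches the edge threshold. Bin j holds
the fraction of blocks that are edge blocks of type j, so the bin sum is
the fraction of edge blocks; non-edge blocks contribute to no bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import Frame
from .tracking import SpatioTemporalSegment

__all__ = [
    "EdgeHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "duration",
    "instability",
    "shape_change",
    "edge_histogram",
    "edge_density",
    "texture_variation",
    "extract_features",
]

FEATURE_NAMES = ("duration", "instability", "shape_change", "edge_density", "texture_variation")

SQRT2 = float(np.sqrt(2.0))

#: MPEG-7 2x2 edge filter coefficients, applied to the block laid out as
#: [[a, b], [c, d]]: vertical, horizontal, 45°, 135°, non-directional.
EDGE_FILTERS = np.array(
    [
        [[1.0, -1.0], [1.0, -1.0]],  # vertical edge
        [[1.0, 1.0], [-1.0, -1.0]],  # horizontal edge
        [[SQRT2, 0.0], [0.0, -SQRT2]],  # 45 degree diagonal
        [[0.0, SQRT2], [-SQRT2, 0.0]],  # 135 degree diagonal
        [[2.0, -2.0], [-2.0, 2.0]],  # non-directional
    ]
)

#: Default edge-strength threshold (MPEG-7 reference T_edge, on a 0-255
#: intensity scale).
DEFAULT_EDGE_THRESHOLD = 11.0


@dataclass
class EdgeHistogram:
    """5-bin oriented edge histogram of one frame of a track."""

    bins: np.ndarray  # (5,) fractions
    n_blocks: int
    valid: bool = True  # False when no complete 2x2 block fits in the mask

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if self.bins.shape != (5,):
            raise ValueError("an edge histogram has exactly five bins")


@dataclass
class FeatureVector:
    """The five validation features of one track."""

    duration: int
    instability: float
    shape_change: float
    edge_density: float
    texture_variation: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def duration(track: SpatioTemporalSegment, mode: str = "span") -> int:
    """Lifetime of a track in frames.

    ``span`` (default) counts ``last − first + 1``; ``present`` counts only
    frames with a detection. Both readings of "number of frames the segment
    can be tracked" are exposed; ``span`` keeps duration consistent with
    the instability definition.
    """
    if mode == "span":
        return track.lifetime
    if mode == "present":
        return len(track.frames_present)
    raise ValueError(f"unknown duration mode {mode!r}")


def instability(track: SpatioTemporalSegment) -> float:
    """Fraction of lifetime frames in which the track has no detection."""
    return len(track.gap_frames) / track.lifetime


def shape_change(areas: Sequence[float]) -> float:
    """Relative span of the per-frame areas, ``(max − min) / max``."""
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size < 1:
        raise ValueError("need at least one area")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    mx = areas.max()
    return float((mx - areas.min()) / mx)


def edge_histogram(
    mask: np.ndarray, gray: np.ndarray, edge_threshold: float = DEFAULT_EDGE_THRESHOLD
) -> EdgeHistogram:
    """5-bin edge histogram of the masked region of a grayscale image.

    The mask's bounding box is tiled into non-overlapping 2×2 blocks; only
    blocks whose four pixels all lie inside the mask are kept. A kept block
    is an edge block of the arg-max filter type iff the maximum absolute
    filter response reaches ``edge_threshold`` (ties go to the
    first-listed orientation). ``gray`` is expected on a 0-255 scale.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    h = (r1 - r0) // 2 * 2
    w = (c1 - c0) // 2 * 2
    if h < 2 or w < 2:
        return EdgeHistogram(bins=np.zeros(5), n_blocks=0, valid=False)
    sub = np.asarray(gray, dtype=np.float64)[r0 : r0 + h, c0 : c0 + w]
    msub = mask[r0 : r0 + h, c0 : c0 + w]
    blocks = sub.reshape(h // 2, 2, w // 2, 2).transpose(0, 2, 1, 3)
    covered = msub.reshape(h // 2, 2, w // 2, 2).transpose(0, 2, 1, 3).all(axis=(2, 3))
    if not covered.any():
        return EdgeHistogram(bins=np.zeros(5), n_blocks=0, valid=False)
    kept = blocks[covered]  # (n, 2, 2)
    responses = np.abs(np.einsum("nij,kij->nk", kept, EDGE_FILTERS))
    strongest = responses.argmax(axis=1)
    is_edge = responses.max(axis=1) >= edge_threshold
    counts = np.bincount(strongest[is_edge], minlength=5)
    n_blocks = int(covered.sum())
    return EdgeHistogram(bins=counts / n_blocks, n_blocks=n_blocks, valid=True)


def edge_density(histograms: Sequence[EdgeHistogram]) -> float:
    """Mean of the summed histograms over the track's frames."""
    if len(histograms) < 1:
        raise ValueError("need at least one histogram")
    return float(np.mean([h.bins.sum() for h in histograms]))


def texture_variation(histograms: Sequence[EdgeHistogram]) -> float:
    """Mean per-bin value range (max − min over frames) of the histograms."""
    if len(histograms) < 1:
        raise ValueError("need at least one histogram")
    bins = np.stack([h.bins for h in histograms])  # (n, 5)
    return float(np.mean(bins.max(axis=0) - bins.min(axis=0)))


def extract_features(
    track: SpatioTemporalSegment,
    frames: Sequence[Frame],
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    duration_mode: str = "span",
) -> FeatureVector:
    """Assemble the five validation features of a track.

    Areas and edge histograms are computed on the frames where the track is
    actually present; gap frames and interpolated masks are excluded, since
    validation precedes gap filling in the pipeline. The grayscale input to
    the edge histograms is the L channel rescaled to 0-255.
    """
    observed = [t for t in track.frames_present if t not in track.interpolated]
    if not observed:
        observed = track.frames_present
    areas = [int(track.masks[t].sum()) for t in observed]
    hists = []
    for t in observed:
        f = frames[t]
        if f.space != "LUV":
            raise ValueError("feature extraction expects LUV frames")
        gray = f.pixels[..., 0] * 2.55  # L* in [0,100] -> [0,255]
        hists.append(edge_histogram(track.masks[t], gray, edge_threshold=edge_threshold))
    return FeatureVector(
        duration=duration(track, mode=duration_mode),
        instability=instability(track),
        shape_change=shape_change(areas),
        edge_density=edge_density(hists),
        texture_variation=texture_variation(hists),
    )
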