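"""Frame preprocessing and color segmentation.

Input frames are downscaled, converted to the perceptually uniform CIE
L*u*v* color space, and partitioned into coherent color segments. The
segmentation is a joint spatial+range mean-shift filtering (flat kernels,
fixed pixel positions) followed by region labeling: adjacent pixels whose
filtered colors lie within the range bandwidth of each other end up in the
same segment. Each surviving segment carries the arithmetic mean of the
*original* LUV colors of its pixels, which is the representative color used
by the color classifier downstream.

Coordinates are (row, col), 0-based, origin top-left. LUV uses the sRGB /
D65 convention of ``skimage.color.rgb2luv``; L* lies in [0, 100].
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from skimage.color import rgb2luv
from skimage.transform import downscale_local_mean, resize
from skimage.util import img_as_float

__all__ = [
    "Frame",
    "Segment",
    "SegmentMap",
    "preprocess_frame",
    "mean_shift_segment",
]


@dataclass
class Frame:
    """One image of a sequence.

    Parameters
    ----------
    index : int
        0-based frame number within the sequence.
    pixels : ndarray, shape (H, W, 3)
        Color values; uint8 or float for RGB, float for LUV.
    space : {"RGB", "LUV"}
        Color space tag.
    """

    index: int
    pixels: np.ndarray
    space: str = "RGB"

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.space not in ("RGB", "LUV"):
            raise ValueError(f"unknown color space {self.space!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Segment:
    """A maximal connected region of similar color in one frame.

    The pixel mask is stored as a bounding-box submask to keep per-frame
    memory proportional to the image, not to ``n_segments * H * W``.
    """

    id: int
    frame_index: int
    area: int
    mean_color: np.ndarray  # (3,) LUV
    shape: tuple[int, int]  # (H, W) of the parent frame
    bbox: tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open
    submask: np.ndarray = field(repr=False)  # bool, (r1-r0, c1-c0)

    @property
    def mask(self) -> np.ndarray:
        """Full-frame boolean mask of the segment."""
        full = np.zeros(self.shape, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        full[r0:r1, c0:c1] = self.submask
        return full

    @property
    def key(self) -> tuple[int, int]:
        """(frame_index, id) — the node key used by the connectivity graph."""
        return (self.frame_index, self.id)


@dataclass
class SegmentMap:
    """Total partition of one frame into color segments."""

    frame_index: int
    labels: np.ndarray  # (H, W) int32, values 0..n_segments-1
    segments: list[Segment]

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, seg_id: int) -> Segment:
        return self.segments[seg_id]


def preprocess_frame(frame: Frame, scale: float = 0.25) -> Frame:
    """Downscale an RGB frame and convert it to LUV.

    Downscaling uses area averaging (exact block means when 1/scale is an
    integer dividing both dimensions, anti-aliased resampling otherwise),
    which preserves mean colors under decimation. The output has dimensions
    ``floor(scale*H) x floor(scale*W)``.
    """
    if frame.space != "RGB":
        raise ValueError("preprocess_frame expects an RGB frame")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    rgb = img_as_float(frame.pixels)
    if scale != 1.0:
        factor = 1.0 / scale
        out_shape = (int(np.floor(scale * frame.height)), int(np.floor(scale * frame.width)))
        if out_shape[0] < 1 or out_shape[1] < 1:
            raise ValueError("scale too small for image size")
        if (
            abs(factor - round(factor)) < 1e-9
            and frame.height % round(factor) == 0
            and frame.width % round(factor) == 0
        ):
            rgb = downscale_local_mean(rgb, (int(round(factor)), int(round(factor)), 1))
        else:
            rgb = resize(rgb, out_shape, order=1, anti_aliasing=True, preserve_range=True)
    luv = rgb2luv(rgb)
    return Frame(index=frame.index, pixels=luv, space="LUV")


def _disk_offsets(radius: float) -> list[tuple[int, int]]:
    r = int(np.floor(radius))
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def _mean_shift_filter(
    luv: np.ndarray, spatial_bandwidth: float, range_bandwidth: float, max_iter: int = 5, tol: float = 0.05
) -> np.ndarray:
    """Joint spatial+range mode filtering with flat kernels.

    Each pixel's color estimate is iteratively replaced by the mean of the
    colors inside its spatial window that lie within the range bandwidth of
    the current estimate. Pixel positions stay fixed; only the range
    component evolves, so estimates converge to local color modes.
    """
    img = luv.astype(np.float32, copy=True)
    H, W, _ = img.shape
    r = int(np.floor(spatial_bandwidth))
    hr2 = np.float32(range_bandwidth * range_bandwidth)
    offsets = _disk_offsets(spatial_bandwidth)
    for _ in range(max_iter):
        padded = np.pad(img, ((r, r), (r, r), (0, 0)), mode="edge")
        acc = np.zeros_like(img)
        cnt = np.zeros((H, W, 1), dtype=np.float32)
        for dy, dx in offsets:
            shifted = padded[r + dy : r + dy + H, r + dx : r + dx + W]
            d2 = np.sum((shifted - img) ** 2, axis=-1)
            m = (d2 <= hr2)[..., None].astype(np.float32)
            acc += shifted * m
            cnt += m
        new = acc / cnt  # cnt >= 1: the center pixel always qualifies
        delta = np.abs(new - img).max()
        img = new
        if delta < tol:
            break
    return img


def _label_similar(filtered: np.ndarray, range_bandwidth: float) -> np.ndarray:
    """4-connected components of pixels with near-identical filtered colors."""
    H, W, _ = filtered.shape
    n = H * W
    idx = np.arange(n, dtype=np.int64).reshape(H, W)
    hr2 = range_bandwidth * range_bandwidth
    rows, cols = [], []
    dh = np.sum((filtered[:, 1:] - filtered[:, :-1]) ** 2, axis=-1) <= hr2
    rows.append(idx[:, 1:][dh])
    cols.append(idx[:, :-1][dh])
    dv = np.sum((filtered[1:] - filtered[:-1]) ** 2, axis=-1) <= hr2
    rows.append(idx[1:][dv])
    cols.append(idx[:-1][dv])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    adj = sparse.coo_matrix((np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels.reshape(H, W)


def _adjacent_label_pairs(labels: np.ndarray) -> np.ndarray:
    """Unique unordered pairs of 4-adjacent distinct labels."""
    pairs = []
    a, b = labels[:, 1:].ravel(), labels[:, :-1].ravel()
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    a, b = labels[1:].ravel(), labels[:-1].ravel()
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    p = np.concatenate(pairs)
    if len(p) == 0:
        return p.reshape(0, 2)
    p = np.sort(p, axis=1)
    return np.unique(p, axis=0)


def _merge_small_regions(labels: np.ndarray, luv: np.ndarray, min_size: int) -> np.ndarray:
    """Merge undersized regions into the most similar-color 4-neighbor.

    Regions smaller than ``min_size`` are processed smallest-first; each is
    absorbed by the adjacent region whose mean LUV color is closest
    (Euclidean), ties broken by the lower region id. A region with no
    neighbor (single-region frame) is kept regardless of size.
    """
    n = int(labels.max()) + 1
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n).astype(np.int64)
    csum = np.zeros((n, 3), dtype=np.float64)
    for ch in range(3):
        csum[:, ch] = np.bincount(flat, weights=luv[..., ch].ravel().astype(np.float64), minlength=n)

    nbrs: list[set[int]] = [set() for _ in range(n)]
    for a, b in _adjacent_label_pairs(labels):
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))

    parent = np.arange(n)
    alive = np.ones(n, dtype=bool)
    heap = [(int(area[i]), i) for i in range(n) if area[i] < min_size]
    heapq.heapify(heap)
    while heap:
        a_i, i = heapq.heappop(heap)
        if not alive[i] or area[i] != a_i or area[i] >= min_size:
            continue
        cand = [j for j in nbrs[i] if alive[j]]
        if not cand:
            continue
        mean_i = csum[i] / area[i]
        best = min(cand, key=lambda j: (float(np.sum((csum[j] / area[j] - mean_i) ** 2)), j))
        alive[i] = False
        parent[i] = best
        area[best] += area[i]
        csum[best] += csum[i]
        for k in nbrs[i]:
            if k != best and alive[k]:
                nbrs[k].discard(i)
                nbrs[k].add(best)
                nbrs[best].add(k)
        nbrs[best].discard(i)
        if area[best] < min_size:
            heapq.heappush(heap, (int(area[best]), best))

    root = np.arange(n)
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        root[i] = r
    return root[labels]


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..m-1 in raster-scan order of first occurrence."""
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = np.argsort(first)
    mapping = np.empty(int(labels.max()) + 1, dtype=np.int32)
    mapping[uniq[order]] = np.arange(len(uniq), dtype=np.int32)
    return mapping[labels]


def mean_shift_segment(
    frame: Frame,
    spatial_bandwidth: float = 8.0,
    range_bandwidth: float = 8.0,
    min_segment_size: int = 20,
    max_iter: int = 5,
) -> SegmentMap:
    """Segment an LUV frame into coherent color regions.

    Parameters
    ----------
    spatial_bandwidth : float
        Radius (pixels) of the flat spatial kernel.
    range_bandwidth : float
        Radius (LUV Euclidean distance) of the flat range kernel.
    min_segment_size : int
        Regions smaller than this many pixels are merged into their most
        similar-color neighbor.
    """
    if frame.space != "LUV":
        raise ValueError("mean_shift_segment expects an LUV frame")
    if spatial_bandwidth <= 0 or range_bandwidth <= 0:
        raise ValueError("bandwidths must be positive")
    if min_segment_size < 1:
        raise ValueError("min_segment_size must be >= 1")

    luv = frame.pixels
    filtered = _mean_shift_filter(luv, spatial_bandwidth, range_bandwidth, max_iter=max_iter)
    labels = _label_similar(filtered, range_bandwidth)
    labels = _merge_small_regions(labels, luv, min_segment_size)
    labels = _compact_labels(labels)

    n = int(labels.max()) + 1
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n)
    means = np.zeros((n, 3), dtype=np.float64)
    for ch in range(3):
        means[:, ch] = np.bincount(flat, weights=luv[..., ch].ravel().astype(np.float64), minlength=n)
    means /= area[:, None]

    slices = ndimage.find_objects(labels + 1)
    segments = []
    shape = labels.shape
    for sid in range(n):
        sl = slices[sid]
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        submask = labels[r0:r1, c0:c1] == sid
        segments.append(
            Segment(
                id=sid,
                frame_index=frame.index,
                area=int(area[sid]),
                mean_color=means[sid],
                shape=shape,
                bbox=(r0, r1, c0, c1),
                submask=submask,
            )
        )
    return SegmentMap(frame_index=frame.index, labels=labels.astype(np.int32), segments=segments)
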