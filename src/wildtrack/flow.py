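"""Dense optical-flow providers and mask warping.

Tracking propagates segment masks between adjacent frames using a dense
per-pixel displacement field. The provider contract is deliberately small
so that tests can inject exact ground-truth flow: ``flow(t_from, t_to)``
returns a ``(2, H, W)`` array of (row, col) displacements mapping pixels of
``t_from`` to positions in ``t_to``, for adjacent frames only.

The default estimator is pyramidal iterative Lucas-Kanade on the L channel
(dense, coarse-to-fine). Masks are warped by nearest-neighbor forward
splatting followed by a single morphological closing pass that fills the
isolated holes splatting can leave.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from scipy.ndimage import binary_closing

__all__ = [
    "FlowProvider",
    "ZeroFlow",
    "ConstantFlow",
    "FieldFlow",
    "EstimatedFlow",
    "warp_mask",
]


class FlowProvider(ABC):
    """Dense displacement fields between adjacent frames."""

    @abstractmethod
    def flow(self, t_from: int, t_to: int) -> np.ndarray:
        """(2, H, W) displacement (drow, dcol) from ``t_from`` to ``t_to``."""

    def _check_adjacent(self, t_from: int, t_to: int) -> None:
        if abs(t_from - t_to) != 1:
            raise ValueError("flow is defined between adjacent frames only")


class ZeroFlow(FlowProvider):
    """Identity motion; every traced mask equals the source mask."""

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape

    def flow(self, t_from: int, t_to: int) -> np.ndarray:
        self._check_adjacent(t_from, t_to)
        return np.zeros((2, *self.shape))


class ConstantFlow(FlowProvider):
    """Uniform translation of ``(drow, dcol)`` per forward frame step."""

    def __init__(self, shape: tuple[int, int], drow: float, dcol: float):
        self.shape = shape
        self.d = np.array([drow, dcol], dtype=np.float64)

    def flow(self, t_from: int, t_to: int) -> np.ndarray:
        self._check_adjacent(t_from, t_to)
        sign = 1.0 if t_to > t_from else -1.0
        out = np.empty((2, *self.shape))
        out[0] = sign * self.d[0]
        out[1] = sign * self.d[1]
        return out


class FieldFlow(FlowProvider):
    """Exact per-frame fields, e.g. emitted by the synthetic generator.

    ``forward[t]`` maps frame t to t+1. Backward fields (``backward[t]``
    maps frame t to t-1) may be supplied explicitly; otherwise the negated
    forward field is used, which is exact for locally rigid translation.
    """

    def __init__(self, forward: list[np.ndarray], backward: list[np.ndarray] | None = None):
        self.forward = forward
        self.backward = backward

    def flow(self, t_from: int, t_to: int) -> np.ndarray:
        self._check_adjacent(t_from, t_to)
        if t_to == t_from + 1:
            return self.forward[t_from]
        if self.backward is not None:
            return self.backward[t_from]
        return -self.forward[t_to]


class EstimatedFlow(FlowProvider):
    """Pyramidal iterative Lucas-Kanade flow estimated from LUV frames."""

    def __init__(self, frames, radius: int = 7, num_warp: int = 5):
        self.frames = frames
        self.radius = radius
        self.num_warp = num_warp
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _gray(self, t: int) -> np.ndarray:
        f = self.frames[t]
        if f.space == "LUV":
            return f.pixels[..., 0]
        return np.asarray(f.pixels, dtype=np.float64).mean(axis=-1)

    def flow(self, t_from: int, t_to: int) -> np.ndarray:
        self._check_adjacent(t_from, t_to)
        key = (t_from, t_to)
        if key not in self._cache:
            from skimage.registration import optical_flow_ilk

            # optical_flow_ilk returns the field that registers the moving
            # image onto the reference: sampling t_from at (r+v, c+u)
            # reconstructs t_to, so -v is the displacement t_from -> t_to.
            v = optical_flow_ilk(
                self._gray(t_to), self._gray(t_from), radius=self.radius, num_warp=self.num_warp
            )
            self._cache[key] = -v
        return self._cache[key]


_CLOSE_STRUCT = np.ones((3, 3), dtype=bool)


def warp_mask(mask: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Propagate a boolean mask by one flow step.

    Nearest-neighbor forward splatting: each set pixel lands on the rounded
    target position (out-of-bounds targets are clipped away), then one
    closing pass fills isolated holes left by the splat.
    """
    H, W = mask.shape
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        return np.zeros_like(mask)
    nr = np.rint(rr + flow[0, rr, cc]).astype(np.intp)
    nc = np.rint(cc + flow[1, rr, cc]).astype(np.intp)
    keep = (nr >= 0) & (nr < H) & (nc >= 0) & (nc < W)
    out = np.zeros_like(mask)
    out[nr[keep], nc[keep]] = True
    if out.any():
        # pad so the closing cannot erode shapes clipped at the image border
        padded = np.pad(out, 2)
        closed = binary_closing(padded, structure=_CLOSE_STRUCT)
        out = closed[2:-2, 2:-2]
    return out
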