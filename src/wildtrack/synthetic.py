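"""Deterministic synthetic wildlife scenes with exact ground truth.

The generator emulates the statistical structure the detection method
relies on, without attempting photorealism:

- low-texture gray-brown foreground blobs (elliptical, slowly moving with
  the scene) standing in for poorly textured animal hides,
- a textured green background with clutter patches, a configurable
  fraction of which is *confusable* — drawn from the foreground palette so
  that color alone cannot separate the classes (the classic failure mode of
  color-only detection) but carrying high-amplitude luminance texture so
  that texture features can,
- optional near-black / near-white low-texture confusers plus shaded and
  highlighted blob parts, which exercise the luminance filter,
- global camera pan (the whole background translates),
- scheduled occlusions that hide a blob for a few frames while the ground
  truth stays continuous (flagged as occluded),
- per-frame sensor noise.

Everything — frames, per-frame ground-truth region masks, and the exact
dense flow fields — is derived from one seeded RNG, so a fixed seed gives
bit-identical output. The flow fields are suitable for injection into the
tracker in place of estimated optical flow.

Palettes are defined in LUV (anchor colors plus uniform LUV jitter) and
rendered through sRGB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import luv2rgb, rgb2luv

from .evaluation import GroundTruth
from .flow import FieldFlow
from .segmentation import Frame, Segment

__all__ = [
    "SceneSpec",
    "SyntheticSequence",
    "generate_sequence",
    "generate_training_images",
]


def _rgb_to_luv1(rgb255: Sequence[float]) -> np.ndarray:
    arr = np.asarray(rgb255, dtype=np.float64).reshape(1, 1, 3) / 255.0
    return rgb2luv(arr)[0, 0]


def _luv_to_rgb255(luv: np.ndarray) -> np.ndarray:
    return np.clip(luv2rgb(np.asarray(luv, dtype=np.float64).reshape(1, 1, 3))[0, 0] * 255.0, 0, 255)


# Anchor colors. Foreground: gray-brown, low chroma (elephant-hide band).
FG_ANCHORS = [_rgb_to_luv1(c) for c in [(125, 115, 105), (105, 95, 88), (140, 126, 112), (92, 84, 76)]]
# Background: greens and olives.
BG_ANCHORS = [_rgb_to_luv1(c) for c in [(88, 128, 58), (66, 108, 48), (108, 120, 56), (52, 88, 40)]]
# Near-black / near-white confuser anchors with a faint brown tint.
DARK_ANCHOR = _rgb_to_luv1((16, 14, 12))
BRIGHT_ANCHOR = _rgb_to_luv1((243, 240, 236))


@dataclass
class SceneSpec:
    """Scene parameters; the defaults are the standard test conditions."""

    width: int = 320
    height: int = 180
    n_frames: int = 24
    n_blobs: int = 3
    blob_ry: tuple[int, int] = (8, 14)  # vertical semi-axis range (px)
    blob_rx: tuple[int, int] = (12, 22)  # horizontal semi-axis range (px)
    blob_speed: float = 0.4  # max own-velocity per axis (px/frame, on top of pan)
    n_clutter: int = 12
    clutter_r: tuple[int, int] = (8, 22)  # clutter patch semi-axis range
    confusable_fraction: float = 0.3  # clutter patches drawn from the fg palette
    pan: tuple[float, float] = (0.0, 2.0)  # background image motion (drow, dcol) px/frame
    bg_texture_amp: float = 12.0  # luminance texture, 8-bit units
    fg_texture_amp: float = 3.0
    confuser_texture_amp: float = 20.0
    noise_sigma: float = 2.0  # per-frame sensor noise, 8-bit units
    occlusions: tuple[tuple[int, int, int], ...] | None = None  # (blob, start, length); None = default
    luminance_confusers: bool = False

    def __post_init__(self) -> None:
        if self.width < 4 * self.blob_rx[1] or self.height < 4 * self.blob_ry[1]:
            raise ValueError("blob larger than frame allows")
        if self.n_frames < 1 or self.n_blobs < 0:
            raise ValueError("inconsistent scene parameters")
        if not 0 <= self.confusable_fraction <= 1:
            raise ValueError("confusable_fraction must be in [0, 1]")

    def resolved_occlusions(self) -> list[tuple[int, int, int]]:
        if self.occlusions is not None:
            occ = list(self.occlusions)
        elif self.n_blobs > 0 and self.n_frames >= 12:
            occ = [(0, self.n_frames // 3, 3)]
        else:
            occ = []
        for blob, start, length in occ:
            if not (0 <= blob < max(self.n_blobs, 1)) or start < 0 or length < 0:
                raise ValueError("inconsistent occlusion schedule")
        return occ


@dataclass
class SyntheticSequence:
    """Frames, ground truth, and exact flow of one generated scene."""

    spec: SceneSpec
    seed: int
    frames: list[Frame]
    gt: GroundTruth
    flow_forward: list[np.ndarray]  # flow_forward[t]: frame t -> t+1, (2, H, W)
    flow_backward: list[np.ndarray]  # flow_backward[t]: frame t -> t-1, (2, H, W)
    blob_colors: list[np.ndarray]  # anchor LUV per blob
    visible_blob_masks: dict[int, list[tuple[int, np.ndarray]]]  # frame -> [(blob, mask)]

    def flow_provider(self) -> FieldFlow:
        return FieldFlow(self.flow_forward, self.flow_backward)

    def candidates_from_truth(self) -> dict[int, list[Segment]]:
        """The rendered per-blob masks as candidate segments.

        Ground-truth candidates let tracking be tested in isolation from
        segmentation and color classification.
        """
        out: dict[int, list[Segment]] = {}
        shape = (self.spec.height, self.spec.width)
        for t, entries in self.visible_blob_masks.items():
            segs = []
            for blob, mask in entries:
                rr, cc = np.nonzero(mask)
                if len(rr) == 0:
                    continue
                r0, r1 = rr.min(), rr.max() + 1
                c0, c1 = cc.min(), cc.max() + 1
                segs.append(
                    Segment(
                        id=blob,
                        frame_index=t,
                        area=int(len(rr)),
                        mean_color=self.blob_colors[blob],
                        shape=shape,
                        bbox=(int(r0), int(r1), int(c0), int(c1)),
                        submask=mask[r0:r1, c0:c1],
                    )
                )
            out[t] = segs
        return out


def _jitter(rng: np.random.Generator, anchor: np.ndarray, scale=(4.0, 3.0, 3.0)) -> np.ndarray:
    return anchor + rng.uniform(-1, 1, 3) * np.asarray(scale)


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _paint_canvas(
    rng: np.random.Generator, spec: SceneSpec, h: int, w: int, band: tuple[float, float]
) -> np.ndarray:
    """Background canvas in RGB float [0, 255] with texture baked in.

    Clutter (including confusable and luminance-confuser patches) is
    restricted to the vertical ``band`` (fractions of the height) so that
    foreground blobs, placed outside it, never touch a confuser.
    """
    color = np.empty((h, w, 3), dtype=np.float64)
    top = _luv_to_rgb255(_jitter(rng, BG_ANCHORS[0]))
    bottom = _luv_to_rgb255(_jitter(rng, BG_ANCHORS[1]))
    grad = np.linspace(0, 1, h)[:, None, None]
    color[:] = top * (1 - grad) + bottom * grad
    amp = np.full((h, w), spec.bg_texture_amp)

    r0, r1 = int(band[0] * h), int(band[1] * h)
    n_conf = int(round(spec.n_clutter * spec.confusable_fraction))
    kinds = ["confusable"] * n_conf + ["bg"] * (spec.n_clutter - n_conf)
    if spec.luminance_confusers:
        kinds += ["dark", "bright", "dark", "bright"]
    for kind in kinds:
        ry = rng.integers(spec.clutter_r[0], spec.clutter_r[1] + 1)
        rx = rng.integers(spec.clutter_r[0], spec.clutter_r[1] + 1)
        cy = rng.uniform(r0 + ry, max(r1 - ry, r0 + ry + 1))
        cx = rng.uniform(rx, w - rx)
        mask = _ellipse_mask(h, w, cy, cx, ry, rx)
        if kind == "bg":
            luv = _jitter(rng, BG_ANCHORS[rng.integers(len(BG_ANCHORS))])
            patch_amp = spec.bg_texture_amp
        elif kind == "confusable":
            luv = _jitter(rng, FG_ANCHORS[rng.integers(len(FG_ANCHORS))])
            patch_amp = spec.confuser_texture_amp
        elif kind == "dark":
            luv = _jitter(rng, DARK_ANCHOR, scale=(1.5, 1.0, 1.0))
            patch_amp = spec.fg_texture_amp
        else:  # bright
            luv = _jitter(rng, BRIGHT_ANCHOR, scale=(1.5, 1.0, 1.0))
            patch_amp = spec.fg_texture_amp
        color[mask] = _luv_to_rgb255(luv)
        amp[mask] = patch_amp

    noise = rng.uniform(-1, 1, (h, w))
    return np.clip(color + (noise * amp)[..., None], 0, 255)


@dataclass
class _Blob:
    ry: int
    rx: int
    start: np.ndarray  # (row, col) float
    vel: np.ndarray  # image velocity (row, col) px/frame
    patch: np.ndarray  # (2ry+1, 2rx+1, 3) RGB float
    mask: np.ndarray  # ellipse mask of the patch
    anchor_luv: np.ndarray

    def center(self, t: int) -> np.ndarray:
        return np.rint(self.start + t * self.vel).astype(int)


def _make_blob(rng: np.random.Generator, spec: SceneSpec, shaded: bool = False) -> _Blob:
    ry = int(rng.integers(spec.blob_ry[0], spec.blob_ry[1] + 1))
    rx = int(rng.integers(spec.blob_rx[0], spec.blob_rx[1] + 1))
    anchor = FG_ANCHORS[rng.integers(len(FG_ANCHORS))]
    luv = _jitter(rng, anchor)
    h, w = 2 * ry + 1, 2 * rx + 1
    patch = np.empty((h, w, 3), dtype=np.float64)
    patch[:] = _luv_to_rgb255(luv)
    mask = _ellipse_mask(h, w, ry, rx, ry, rx)
    if shaded:
        # a near-black shaded part and a near-white highlight on the hide
        dark = _ellipse_mask(h, w, ry + ry // 2, rx // 2, ry // 2 + 1, rx // 2 + 1)
        bright = _ellipse_mask(h, w, ry // 2, w - rx // 2, ry // 2 + 1, rx // 2 + 1)
        patch[dark & mask] = _luv_to_rgb255(_jitter(rng, DARK_ANCHOR, scale=(1.5, 1.0, 1.0)))
        patch[bright & mask] = _luv_to_rgb255(_jitter(rng, BRIGHT_ANCHOR, scale=(1.5, 1.0, 1.0)))
    patch += rng.uniform(-1, 1, (h, w))[..., None] * spec.fg_texture_amp
    patch = np.clip(patch, 0, 255)
    return _Blob(ry=ry, rx=rx, start=np.zeros(2), vel=np.zeros(2), patch=patch, mask=mask, anchor_luv=luv)


def _place_blobs(rng: np.random.Generator, spec: SceneSpec, blobs: list[_Blob]) -> None:
    """Assign non-overlapping start positions inside the blob band."""
    pan = np.asarray(spec.pan)
    placed: list[tuple[np.ndarray, int]] = []
    for blob in blobs:
        vel = pan + rng.uniform(-spec.blob_speed, spec.blob_speed, 2)
        drift = vel * (spec.n_frames - 1)
        lo_r = blob.ry + 2 + max(-drift[0], 0)
        hi_r = min(spec.height * 0.55, spec.height - blob.ry - 2 - max(drift[0], 0))
        lo_c = blob.rx + 2 + max(-drift[1], 0)
        hi_c = spec.width - blob.rx - 2 - max(drift[1], 0)
        if hi_r <= lo_r or hi_c <= lo_c:
            raise ValueError("blob trajectory does not fit in the frame")
        for _ in range(300):
            pos = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            sep = all(
                np.abs(pos - p).max() > (r + max(blob.ry, blob.rx) + 6) for p, r in placed
            )
            if sep:
                break
        placed.append((pos, max(blob.ry, blob.rx)))
        blob.start = pos
        blob.vel = vel


def generate_sequence(spec: SceneSpec | None = None, seed: int = 0) -> SyntheticSequence:
    """Render a scene and emit frames, ground truth, and exact flow."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    H, W, T = spec.height, spec.width, spec.n_frames

    # integer background shift per frame (cumulative rounding keeps flow exact)
    shifts = np.stack(
        [np.rint(np.arange(T) * spec.pan[0]), np.rint(np.arange(T) * spec.pan[1])], axis=1
    ).astype(int)
    base = shifts.max(axis=0)
    extent = shifts.max(axis=0) - shifts.min(axis=0)
    canvas = _paint_canvas(rng, spec, H + extent[0], W + extent[1], band=(0.62, 0.97))

    blobs = [_make_blob(rng, spec, shaded=spec.luminance_confusers) for _ in range(spec.n_blobs)]
    _place_blobs(rng, spec, blobs)

    occl = spec.resolved_occlusions()
    hidden: dict[int, set[int]] = {t: set() for t in range(T)}
    for blob, start, length in occl:
        for t in range(start, min(start + length, T)):
            hidden[t].add(blob)

    frames: list[Frame] = []
    gt_labels: dict[int, np.ndarray] = {}
    gt_occluded: dict[int, set[int]] = {}
    visible_masks: dict[int, list[tuple[int, np.ndarray]]] = {}
    blob_frame_masks: list[list[np.ndarray]] = []  # [t][blob] mask (incl. occluded)

    for t in range(T):
        o = base - shifts[t]
        img = canvas[o[0] : o[0] + H, o[1] : o[1] + W].copy()
        visible_masks[t] = []
        masks_t = []
        for b, blob in enumerate(blobs):
            cy, cx = blob.center(t)
            full = np.zeros((H, W), dtype=bool)
            r0, c0 = cy - blob.ry, cx - blob.rx
            full[r0 : r0 + blob.mask.shape[0], c0 : c0 + blob.mask.shape[1]] = blob.mask
            masks_t.append(full)
            if b not in hidden[t]:
                img[full] = blob.patch[blob.mask]
                visible_masks[t].append((b, full))
        blob_frame_masks.append(masks_t)

        if spec.noise_sigma > 0:
            img = img + rng.normal(0, spec.noise_sigma, img.shape)
        frames.append(Frame(index=t, pixels=np.clip(img, 0, 255).astype(np.uint8), space="RGB"))

        union = np.zeros((H, W), dtype=bool)
        for m in masks_t:
            union |= m
        lab, n_reg = ndimage.label(union)
        gt_labels[t] = lab.astype(np.int32)
        occ_ids = set()
        for rid in range(1, n_reg + 1):
            members = [b for b, m in enumerate(masks_t) if m[lab == rid].any()]
            if members and all(b in hidden[t] for b in members):
                occ_ids.add(rid)
        gt_occluded[t] = occ_ids

    flow_forward: list[np.ndarray] = []
    for t in range(T - 1):
        d = (shifts[t + 1] - shifts[t]).astype(np.float32)
        fwd = np.empty((2, H, W), dtype=np.float32)
        fwd[0] = d[0]
        fwd[1] = d[1]
        for b, blob in enumerate(blobs):
            bd = (blob.center(t + 1) - blob.center(t)).astype(np.float32)
            m = blob_frame_masks[t][b]
            fwd[0][m] = bd[0]
            fwd[1][m] = bd[1]
        flow_forward.append(fwd)
    # flow_backward[t] maps frame t -> t-1; entry 0 is a zero placeholder
    flow_backward = [np.zeros((2, H, W), dtype=np.float32)]
    for t in range(1, T):
        d = (shifts[t] - shifts[t - 1]).astype(np.float32)
        bwd = np.empty((2, H, W), dtype=np.float32)
        bwd[0] = -d[0]
        bwd[1] = -d[1]
        for b, blob in enumerate(blobs):
            bd = (blob.center(t) - blob.center(t - 1)).astype(np.float32)
            m = blob_frame_masks[t][b]
            bwd[0][m] = -bd[0]
            bwd[1][m] = -bd[1]
        flow_backward.append(bwd)

    return SyntheticSequence(
        spec=spec,
        seed=seed,
        frames=frames,
        gt=GroundTruth(labels=gt_labels, occluded=gt_occluded),
        flow_forward=flow_forward,
        flow_backward=flow_backward,
        blob_colors=[b.anchor_luv for b in blobs],
        visible_blob_masks=visible_masks,
    )


def generate_training_images(
    spec: SceneSpec | None = None, seed: int = 0, n_images: int = 16
) -> list[tuple[Frame, np.ndarray]]:
    """Annotated (image, foreground mask) pairs for color-model training.

    Every image is an independent single-frame scene — fresh background
    with clutter (including confusable patches, reproducing the
    foreground/background color asymmetry) and one or two foreground blobs
    whose pixels define the mask. With ``luminance_confusers`` enabled the
    blobs carry shaded/highlighted parts, so the foreground color list
    contains near-black and near-white entries for the luminance filter to
    remove. 10-20 images is the intended regime.
    """
    spec = spec or SceneSpec()
    if not 1 <= n_images <= 50:
        raise ValueError("n_images out of range")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        sub = np.random.default_rng(rng.integers(2**31))
        canvas = _paint_canvas(sub, spec, spec.height, spec.width, band=(0.55, 0.97))
        n_blobs = int(sub.integers(1, 3))
        blobs = [_make_blob(sub, spec, shaded=spec.luminance_confusers) for _ in range(n_blobs)]
        one = replace(spec, n_frames=1, n_blobs=n_blobs)
        _place_blobs(sub, one, blobs)
        mask = np.zeros((spec.height, spec.width), dtype=bool)
        img = canvas
        for blob in blobs:
            cy, cx = blob.center(0)
            full = np.zeros_like(mask)
            r0, c0 = cy - blob.ry, cx - blob.rx
            full[r0 : r0 + blob.mask.shape[0], c0 : c0 + blob.mask.shape[1]] = blob.mask
            img[full] = blob.patch[blob.mask]
            mask |= full
        if spec.noise_sigma > 0:
            img = img + sub.normal(0, spec.noise_sigma, img.shape)
        out.append((Frame(index=i, pixels=np.clip(img, 0, 255).astype(np.uint8), space="RGB"), mask))
    return out
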