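"""Trainable foreground/background color model.

A discriminative color model is learned from a handful of labeled training
images: each image is split into a foreground and a background image by a
binary mask, both sides are segmented independently, and the per-segment
mean LUV colors form the two training lists. The default backend is an
RBF-kernel SVM with asymmetric misclassification costs: the foreground
class is made more expensive to miss, which deliberately trades false
positives (handled later by spatiotemporal validation) for a high detection
rate. The RBF width is selected so that the number of support vectors is
minimal, which favors a low-complexity decision boundary.

Near-black and near-white colors carry unreliable class information, so a
luminance filter can drop them from the foreground list before training.

Segments are classified either by their mean color alone (one-stage) or by
a per-pixel vote (two-stage): a segment is a candidate iff strictly more
than ``vote_threshold`` (default 2/3) of its pixels are classified as
foreground.
"""

from __future__ import annotations

import base64
import json
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .segmentation import Frame, Segment, SegmentMap, mean_shift_segment, preprocess_frame

__all__ = [
    "ColorSample",
    "ColorModel",
    "extract_training_colors",
    "luminance_filter",
    "train_color_model",
    "classify_segment",
    "detect_candidates",
    "save_model",
    "load_model",
]

FOREGROUND = "foreground"
BACKGROUND = "background"

#: Theoretical range of L* in the LUV encoding used throughout the package.
L_RANGE = (0.0, 100.0)

#: Default RBF-width grid: logarithmic, six decades.
DEFAULT_GAMMA_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass
class ColorSample:
    """A single labeled LUV color observation."""

    color: np.ndarray  # (3,) LUV
    label: str  # FOREGROUND or BACKGROUND
    source: str = "segment_mean"  # or "pixel"

    def __post_init__(self) -> None:
        self.color = np.asarray(self.color, dtype=np.float64)
        if self.color.shape != (3,) or not np.all(np.isfinite(self.color)):
            raise ValueError("color must be a finite LUV 3-vector")
        if self.label not in (FOREGROUND, BACKGROUND):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ColorModel:
    """A trained binary decision function over LUV colors."""

    classifier: object  # fitted sklearn-style estimator, predict() -> {0, 1}
    gamma: float | None
    cost_ratio: float
    luminance_limits: tuple[float, float]
    cv_error: float  # fivefold cross-validation accuracy on the training set
    backend: str = "rbf_svm"
    n_support: int | None = None

    def predict_colors(self, colors: np.ndarray) -> np.ndarray:
        """Boolean foreground predictions for an (N, 3) array of LUV colors."""
        colors = np.atleast_2d(np.asarray(colors, dtype=np.float64))
        return self.classifier.predict(colors).astype(bool)


def _segment_side(
    frame: Frame,
    side_mask: np.ndarray,
    scale: float,
    spatial_bandwidth: float,
    range_bandwidth: float,
    min_segment_size: int,
) -> list[np.ndarray]:
    """Segment one side (fg or bg) of a training image in isolation.

    The other side is blanked to black before preprocessing; segments that
    fall mostly on the blanked filler are discarded, the rest contribute
    their mean LUV color.
    """
    pixels = frame.pixels.copy()
    pixels[~side_mask] = 0
    luv = preprocess_frame(Frame(frame.index, pixels, "RGB"), scale=scale)
    if scale != 1.0:
        from skimage.transform import resize

        small = resize(side_mask.astype(float), luv.pixels.shape[:2], order=1, anti_aliasing=False) > 0.5
    else:
        small = side_mask
    seg_map = mean_shift_segment(
        luv,
        spatial_bandwidth=spatial_bandwidth,
        range_bandwidth=range_bandwidth,
        min_segment_size=min_segment_size,
    )
    colors = []
    for seg in seg_map:
        inside = np.count_nonzero(small[seg.mask])
        if inside / seg.area >= 0.5:
            colors.append(seg.mean_color)
    return colors


def extract_training_colors(
    image: Frame,
    label_mask: np.ndarray,
    scale: float = 0.25,
    spatial_bandwidth: float = 8.0,
    range_bandwidth: float = 8.0,
    min_segment_size: int = 20,
) -> list[ColorSample]:
    """Extract labeled mean-segment colors from one annotated training image.

    The image is split into a foreground image and a background image by the
    binary mask; each side is preprocessed and segmented independently and
    every resulting segment yields one sample carrying its side's label.
    """
    label_mask = np.asarray(label_mask, dtype=bool)
    if label_mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask dimensions must match the image")
    samples: list[ColorSample] = []
    if not label_mask.any():
        warnings.warn("all-background mask: only background samples produced")
    elif label_mask.all():
        warnings.warn("all-foreground mask: only foreground samples produced")
    for side_mask, label in ((label_mask, FOREGROUND), (~label_mask, BACKGROUND)):
        if not side_mask.any():
            continue
        for color in _segment_side(
            image, side_mask, scale, spatial_bandwidth, range_bandwidth, min_segment_size
        ):
            samples.append(ColorSample(color=color, label=label))
    return samples


def luminance_filter(
    samples: Sequence[ColorSample], lower_pct: float, upper_pct: float
) -> list[ColorSample]:
    """Drop foreground samples with near-black or near-white luminance.

    A foreground sample is removed when its L* lies below ``lower_pct`` or
    above ``upper_pct`` of the theoretical L range [0, 100]. Background
    samples pass through untouched. ``(0, 100)`` is the identity.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    lo = L_RANGE[0] + lower_pct / 100.0 * (L_RANGE[1] - L_RANGE[0])
    hi = L_RANGE[0] + upper_pct / 100.0 * (L_RANGE[1] - L_RANGE[0])
    out = []
    for s in samples:
        if s.label == FOREGROUND and (s.color[0] < lo or s.color[0] > hi):
            continue
        out.append(s)
    return out


def train_color_model(
    samples: Sequence[ColorSample],
    cost_ratio: float = 2.0,
    gamma_grid: Sequence[float] | None = None,
    luminance_limits: tuple[float, float] = (0.0, 100.0),
    svm_C: float = 1.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> ColorModel:
    """Fit the RBF-SVM color model.

    The luminance filter is applied to the foreground list first. For every
    gamma in the grid an SVM is fitted with foreground misclassification
    cost ``cost_ratio`` times the background cost; the gamma whose model
    uses the fewest support vectors wins, ties going to the smaller gamma
    (smoother boundary). The recorded ``cv_error`` is the stratified
    fivefold cross-validation accuracy of the winning configuration.
    """
    if cost_ratio < 1:
        raise ValueError("cost_ratio must be >= 1")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    gamma_grid = sorted(float(g) for g in gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma_grid must be non-empty")

    filtered = luminance_filter(samples, *luminance_limits)
    fg = [s.color for s in filtered if s.label == FOREGROUND]
    bg = [s.color for s in filtered if s.label == BACKGROUND]
    if not fg:
        raise ValueError("no foreground samples remain after luminance filtering")
    if not bg:
        raise ValueError("both classes must be present")
    X = np.vstack([fg, bg])
    y = np.concatenate([np.ones(len(fg), dtype=int), np.zeros(len(bg), dtype=int)])

    # The background list is much longer than the foreground list (more
    # segments per image), so the asymmetric cost is applied on top of
    # inverse-class-frequency balancing: without it the class prior swamps
    # any moderate cost ratio and the foreground is simply ignored.
    weights = {1: cost_ratio * len(bg) / len(fg), 0: 1.0}

    def _make(gamma: float) -> SVC:
        return SVC(kernel="rbf", gamma=gamma, C=svm_C, class_weight=weights, random_state=seed)

    folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed) if folds >= 2 else None

    # Support vectors are only worth minimizing among gammas that separate
    # the two classes well: a near-degenerate boundary can be "sparse"
    # while missing one class entirely. Eligibility is judged by balanced
    # cross-validated accuracy (insensitive to the fg/bg imbalance), then
    # the sparsest model wins, ties going to the smaller gamma.
    fits = []
    for gamma in gamma_grid:
        clf = _make(gamma)
        clf.fit(X, y)
        if cv is not None:
            bal = float(
                cross_val_score(_make(gamma), X, y, cv=cv, scoring="balanced_accuracy").mean()
            )
        else:
            bal = float(clf.score(X, y))
        fits.append((int(clf.n_support_.sum()), gamma, clf, bal))
    best_bal = max(f[3] for f in fits)
    eligible = [f for f in fits if f[3] >= best_bal - 0.02]
    n_sv, gamma, clf, _ = min(eligible, key=lambda f: (f[0], f[1]))

    if cv is not None:
        cv_acc = float(cross_val_score(clone(clf), X, y, cv=cv, scoring="accuracy").mean())
    else:
        cv_acc = float("nan")

    return ColorModel(
        classifier=clf,
        gamma=gamma,
        cost_ratio=cost_ratio,
        luminance_limits=tuple(luminance_limits),
        cv_error=cv_acc,
        backend="rbf_svm",
        n_support=n_sv,
    )


def classify_segment(
    model: ColorModel,
    segment: Segment,
    frame: Frame,
    mode: str = "two_stage",
    vote_threshold: float = 2.0 / 3.0,
) -> bool:
    """Decide whether one segment is a candidate detection.

    ``one_stage`` classifies the segment's mean LUV color; ``two_stage``
    classifies every covered pixel and accepts iff the fraction of positive
    pixels is strictly above ``vote_threshold``.
    """
    if frame.space != "LUV":
        raise ValueError("classification operates on LUV frames")
    if segment.frame_index != frame.index:
        raise ValueError("segment does not belong to this frame")
    if mode == "one_stage":
        return bool(model.predict_colors(segment.mean_color[None])[0])
    if mode == "two_stage":
        if not 0 < vote_threshold < 1:
            raise ValueError("vote_threshold must be in (0, 1)")
        pixels = frame.pixels[segment.mask]
        frac = float(model.predict_colors(pixels).mean())
        return frac > vote_threshold
    raise ValueError(f"unknown mode {mode!r}")


def detect_candidates(
    model: ColorModel,
    seg_map: SegmentMap,
    frame: Frame,
    mode: str = "two_stage",
    vote_threshold: float = 2.0 / 3.0,
) -> list[Segment]:
    """All segments of a frame that the color model accepts.

    Equivalent to filtering with :func:`classify_segment`, but two-stage
    voting classifies the whole frame's pixels in one batch and tallies the
    per-segment vote with a label histogram.
    """
    if frame.space != "LUV":
        raise ValueError("classification operates on LUV frames")
    if seg_map.frame_index != frame.index:
        raise ValueError("segment map does not belong to this frame")
    if mode == "one_stage":
        means = np.stack([s.mean_color for s in seg_map.segments])
        keep = model.predict_colors(means)
        return [s for s, k in zip(seg_map.segments, keep) if k]
    if mode == "two_stage":
        if not 0 < vote_threshold < 1:
            raise ValueError("vote_threshold must be in (0, 1)")
        n = len(seg_map.segments)
        preds = model.predict_colors(frame.pixels.reshape(-1, 3)).astype(np.float64)
        pos = np.bincount(seg_map.labels.ravel(), weights=preds, minlength=n)
        areas = np.array([s.area for s in seg_map.segments], dtype=np.float64)
        frac = pos / areas
        return [s for s, f in zip(seg_map.segments, frac) if f > vote_threshold]
    raise ValueError(f"unknown mode {mode!r}")


_FORMAT_VERSION = 1


def save_model(model: ColorModel, path: str) -> None:
    """Serialize a color model to a single self-describing JSON file.

    The fitted estimator is stored as a base64-encoded pickle payload next
    to a plain-text header with the hyperparameters.
    """
    doc = {
        "format_version": _FORMAT_VERSION,
        "backend": model.backend,
        "gamma": model.gamma,
        "cost_ratio": model.cost_ratio,
        "luminance_limits": list(model.luminance_limits),
        "cv_error": model.cv_error,
        "n_support": model.n_support,
        "payload": base64.b64encode(pickle.dumps(model.classifier)).decode("ascii"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> ColorModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    clf = pickle.loads(base64.b64decode(doc["payload"]))
    return ColorModel(
        classifier=clf,
        gamma=doc["gamma"],
        cost_ratio=doc["cost_ratio"],
        luminance_limits=tuple(doc["luminance_limits"]),
        cv_error=doc["cv_error"],
        backend=doc["backend"],
        n_support=doc["n_support"],
    )
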