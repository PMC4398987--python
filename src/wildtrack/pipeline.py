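"""End-to-end detection pipeline.

Stage order is fixed: preprocess -> segment -> color-classify ->
trace/intersect -> connectivity graph -> subgraphs -> spatial merge ->
spatiotemporal features -> validate -> fill gaps -> (optional) evaluate.
Validation thresholds can be supplied, or calibrated from labeled
ground-truth sequences using the safe-value procedure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .color_model import ColorModel, detect_candidates, extract_training_colors, train_color_model
from .evaluation import GroundTruth, detection_rate, false_positive_rate, match_detections
from .flow import EstimatedFlow, FlowProvider
from .postprocess import fill_gaps
from .segmentation import Frame, mean_shift_segment, preprocess_frame
from .st_features import FEATURE_NAMES, extract_features
from .tracking import SpatioTemporalSegment, track_candidates
from .validation import ThresholdRule, calibrate_rules, validate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "train_model_from_images"]


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline, with their defaults."""

    scale: float = 0.25
    spatial_bandwidth: float = 8.0
    range_bandwidth: float = 8.0
    min_segment_size: int = 150
    mode: str = "two_stage"  # or "one_stage"
    vote_threshold: float = 2.0 / 3.0
    cost_ratio: float = 2.0
    luminance_limits: tuple[float, float] = (0.0, 100.0)
    w: int = 5  # temporal analysis window (frames, each direction)
    C: float = 0.5  # trace-intersection confidence threshold
    features: tuple[str, ...] = FEATURE_NAMES
    duration_mode: str = "span"
    edge_threshold: float = 11.0
    min_overlap: float = 0.0
    validation: bool = True
    fill_gaps: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["luminance_limits"] = list(d["luminance_limits"])
        d["features"] = list(d["features"])
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tracks: list[SpatioTemporalSegment]  # all tracks, pre-validation
    validated_tracks: list[SpatioTemporalSegment]  # post-validation (+ gap filling)
    features: pd.DataFrame  # one row per track
    rules: list[ThresholdRule]
    report: dict

    @property
    def detection_rate(self) -> float | None:
        return self.report.get("detection_rate")

    @property
    def false_positive_rate(self) -> float | None:
        return self.report.get("false_positive_rate")


def train_model_from_images(
    pairs: Sequence[tuple[Frame, np.ndarray]], config: PipelineConfig, seed: int = 0
) -> ColorModel:
    """Train the color model from (image, foreground-mask) pairs."""
    samples = []
    for image, mask in pairs:
        samples.extend(
            extract_training_colors(
                image,
                mask,
                scale=config.scale,
                spatial_bandwidth=config.spatial_bandwidth,
                range_bandwidth=config.range_bandwidth,
                min_segment_size=config.min_segment_size,
            )
        )
    return train_color_model(
        samples,
        cost_ratio=config.cost_ratio,
        luminance_limits=config.luminance_limits,
        seed=seed,
    )


def _rescale_gt(gt: GroundTruth, shape: tuple[int, int]) -> GroundTruth:
    from skimage.transform import resize

    labels = {}
    for t, lab in gt.labels.items():
        if lab.shape == shape:
            labels[t] = lab
        else:
            labels[t] = resize(lab, shape, order=0, preserve_range=True, anti_aliasing=False).astype(lab.dtype)
    return GroundTruth(labels=labels, occluded=gt.occluded)


def _detections_by_frame(tracks: Sequence[SpatioTemporalSegment]) -> dict[int, list[np.ndarray]]:
    out: dict[int, list[np.ndarray]] = {}
    for track in tracks:
        for t, mask in track.masks.items():
            out.setdefault(t, []).append(mask)
    return out


def _label_track(track: SpatioTemporalSegment, gt: GroundTruth) -> bool:
    """A track counts as a true detection when most of its per-frame masks
    coincide with a ground-truth region."""
    hits = 0
    observed = [t for t in track.frames_present if t not in track.interpolated]
    for t in observed:
        if t in gt.labels and (gt.labels[t][track.masks[t]] > 0).any():
            hits += 1
    return hits / len(observed) > 0.5


def run_pipeline(
    frames: Sequence[Frame],
    model: ColorModel,
    config: PipelineConfig | None = None,
    flow_provider: FlowProvider | None = None,
    gt: GroundTruth | None = None,
    rules: Sequence[ThresholdRule] | None = None,
) -> PipelineResult:
    """Run detection and tracking over an RGB frame sequence.

    When ``rules`` is None and ground truth is available, safe thresholds
    are calibrated on this sequence's labeled tracks; without ground truth,
    validation is skipped unless rules are supplied. The report carries
    per-stage counts and, when ground truth is given, detection and
    false-positive rates before and after validation.
    """
    config = config or PipelineConfig()
    if not frames:
        raise ValueError("empty frame sequence")

    luv_frames = [preprocess_frame(f, scale=config.scale) for f in frames]
    shape = luv_frames[0].pixels.shape[:2]
    if gt is not None:
        gt = _rescale_gt(gt, shape)

    seg_maps = [
        mean_shift_segment(
            f,
            spatial_bandwidth=config.spatial_bandwidth,
            range_bandwidth=config.range_bandwidth,
            min_segment_size=config.min_segment_size,
        )
        for f in luv_frames
    ]
    candidates_by_frame = {
        f.index: detect_candidates(model, sm, f, mode=config.mode, vote_threshold=config.vote_threshold)
        for f, sm in zip(luv_frames, seg_maps)
    }

    if flow_provider is None:
        flow_provider = EstimatedFlow(luv_frames)
    tracks, graph = track_candidates(
        candidates_by_frame, len(frames), flow_provider, w=config.w, C=config.C
    )

    rows = []
    for track in tracks:
        fv = extract_features(
            track, luv_frames, edge_threshold=config.edge_threshold, duration_mode=config.duration_mode
        )
        row = {"track_id": track.track_id, **fv.as_dict()}
        if gt is not None:
            row["label"] = _label_track(track, gt)
        rows.append(row)
    features = pd.DataFrame(rows)

    rules = list(rules) if rules is not None else None
    reject_all = False
    if config.validation and rules is None and gt is not None and len(features):
        if features["label"].any():
            rules = calibrate_rules(features, features=config.features)
        else:
            # no true calibration detections: the minimal safe subset is
            # empty, so every track is rejected
            reject_all = True
    if reject_all:
        rules = []
        validated: list[SpatioTemporalSegment] = []
    elif config.validation and rules:
        validated = [
            t
            for t, (_, row) in zip(tracks, features.iterrows())
            if validate({k: row[k] for k in FEATURE_NAMES}, rules)
        ]
    else:
        rules = rules or []
        validated = list(tracks)

    if config.fill_gaps:
        validated = [fill_gaps(t, flow_provider) for t in validated]

    report = {
        "config_hash": config.config_hash,
        "n_frames": len(frames),
        "n_segments": int(sum(len(sm) for sm in seg_maps)),
        "n_candidates": int(sum(len(c) for c in candidates_by_frame.values())),
        "n_links": graph.number_of_edges(),
        "n_tracks": len(tracks),
        "n_validated_tracks": len(validated),
    }
    if gt is not None:
        before = match_detections(_detections_by_frame(tracks), gt, min_overlap=config.min_overlap)
        after = match_detections(_detections_by_frame(validated), gt, min_overlap=config.min_overlap)
        has_regions = gt.n_regions > 0
        report["detection_rate_unvalidated"] = detection_rate(before, gt) if has_regions else None
        report["false_positive_rate_unvalidated"] = false_positive_rate(before)
        report["detection_rate"] = detection_rate(after, gt) if has_regions else None
        report["false_positive_rate"] = false_positive_rate(after)

    return PipelineResult(
        config=config,
        tracks=tracks,
        validated_tracks=validated,
        features=features,
        rules=rules,
        report=report,
    )
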