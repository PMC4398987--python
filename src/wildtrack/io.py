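"""File formats: frame directories, label masks, track JSON, feature CSV.

Frames live as zero-padded numbered PNG/JPEG files in a directory. Ground
truth and debug segmentations are 16-bit PNG label images plus a JSON
manifest. Tracks are exported as one JSON document per sequence with
run-length-encoded per-frame masks.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .evaluation import GroundTruth
from .segmentation import Frame, SegmentMap
from .tracking import SpatioTemporalSegment

__all__ = [
    "read_frames",
    "write_frames",
    "write_ground_truth",
    "read_ground_truth",
    "write_segment_map",
    "rle_encode",
    "rle_decode",
    "tracks_to_json",
    "tracks_from_json",
    "write_feature_table",
]

_IMG_EXT = (".png", ".jpg", ".jpeg")


def read_frames(directory: str) -> list[Frame]:
    """Load an RGB frame sequence from numbered image files."""
    names = sorted(n for n in os.listdir(directory) if n.lower().endswith(_IMG_EXT))
    if not names:
        raise FileNotFoundError(f"no image files in {directory}")
    frames = []
    for i, name in enumerate(names):
        pixels = iio.imread(os.path.join(directory, name))
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        frames.append(Frame(index=i, pixels=pixels[..., :3], space="RGB"))
    return frames


def write_frames(directory: str, frames: Sequence[Frame]) -> None:
    os.makedirs(directory, exist_ok=True)
    for f in frames:
        iio.imwrite(os.path.join(directory, f"frame_{f.index:05d}.png"), np.asarray(f.pixels, dtype=np.uint8))


def write_ground_truth(directory: str, gt: GroundTruth) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = {"frames": {}, "occluded": {str(t): sorted(ids) for t, ids in gt.occluded.items()}}
    for t, lab in gt.labels.items():
        name = f"gt_{t:05d}.png"
        iio.imwrite(os.path.join(directory, name), lab.astype(np.uint16))
        manifest["frames"][str(t)] = name
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)


def read_ground_truth(directory: str) -> GroundTruth:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    labels = {
        int(t): iio.imread(os.path.join(directory, name)).astype(np.int32)
        for t, name in manifest["frames"].items()
    }
    occluded = {int(t): set(ids) for t, ids in manifest.get("occluded", {}).items()}
    return GroundTruth(labels=labels, occluded=occluded)


def write_segment_map(directory: str, seg_map: SegmentMap) -> None:
    """Debug export: 16-bit label PNG plus a per-segment CSV row."""
    os.makedirs(directory, exist_ok=True)
    iio.imwrite(
        os.path.join(directory, f"labels_{seg_map.frame_index:05d}.png"),
        seg_map.labels.astype(np.uint16),
    )
    rows = [
        {
            "frame": seg_map.frame_index,
            "id": s.id,
            "area": s.area,
            "L": s.mean_color[0],
            "U": s.mean_color[1],
            "V": s.mean_color[2],
        }
        for s in seg_map.segments
    ]
    path = os.path.join(directory, "segments.csv")
    pd.DataFrame(rows).to_csv(path, mode="a", header=not os.path.exists(path), index=False)


def rle_encode(mask: np.ndarray) -> list[int]:
    """Row-major run lengths, starting with a run of zeros (may be 0)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    runs = np.diff(np.concatenate([[0], changes, [flat.size]])).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def tracks_to_json(tracks: Sequence[SpatioTemporalSegment], shape: tuple[int, int], path: str) -> None:
    doc = {
        "shape": list(shape),
        "tracks": [
            {
                "track_id": t.track_id,
                "frames": [
                    {
                        "frame": fr,
                        "interpolated": fr in t.interpolated,
                        "rle": rle_encode(t.masks[fr]),
                    }
                    for fr in t.frames_present
                ],
            }
            for t in tracks
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def tracks_from_json(path: str) -> tuple[list[SpatioTemporalSegment], tuple[int, int]]:
    with open(path) as fh:
        doc = json.load(fh)
    shape = tuple(doc["shape"])
    tracks = []
    for td in doc["tracks"]:
        masks = {fd["frame"]: rle_decode(fd["rle"], shape) for fd in td["frames"]}
        interp = {fd["frame"] for fd in td["frames"] if fd["interpolated"]}
        tracks.append(SpatioTemporalSegment(track_id=td["track_id"], masks=masks, interpolated=interp))
    return tracks, shape


def write_feature_table(features: pd.DataFrame, path: str) -> None:
    features.to_csv(path, index=False)


def write_graphml(graph, path: str) -> None:
    """Debug export of a connectivity graph.

    Node keys become "frame:id" strings with frame/segment attributes;
    the non-serializable segment objects are dropped.
    """
    import networkx as nx

    out = nx.Graph()
    for (frame, seg_id) in graph.nodes:
        out.add_node(f"{frame}:{seg_id}", frame=int(frame), segment=int(seg_id))
    for a, b, data in graph.edges(data=True):
        out.add_edge(f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", confidence=float(data["confidence"]))
    nx.write_graphml(out, path)
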