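"""Linking candidate segments across frames into spatiotemporal tracks.

The tracker makes no attempt to match segments one-to-one; frame-wise color
segmentations are temporally unstable (segments split and merge), so the
scheme works with set overlap instead:

1. *Tracing* — each candidate segment's mask is propagated frame-to-frame
   by optical flow, up to ``w`` frames forward and backward.
2. *Trace intersection* — in every window frame the traced mask is compared
   against the candidates there with the Jaccard coefficient
   ``c = |T ∩ S| / |T ∪ S|``; a temporal link is kept iff ``c > C``. Links
   may span several frames, bridging short detection gaps.
3. *Connectivity graph* — candidates are nodes, links are undirected edges
   (forward/backward orientation carries no information); splits and merges
   show up as cycles.
4. *Subgraph extraction + spatial merging* — each connected component is
   one track; member masks in the same frame are unioned, giving one merged
   mask per frame the component touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .flow import FlowProvider, warp_mask
from .segmentation import Segment

__all__ = [
    "Trace",
    "TemporalLink",
    "SpatioTemporalSegment",
    "jaccard_confidence",
    "trace_segment",
    "intersect_trace",
    "build_connectivity_graph",
    "extract_subgraphs",
    "merge_subgraph",
    "track_candidates",
]

NodeKey = tuple[int, int]  # (frame_index, segment_id)


@dataclass
class Trace:
    """Flow-propagated estimates of one segment's mask over ±w frames.

    ``masks`` maps a signed frame offset (−w..−1, +1..+w) to the estimated
    boolean mask; offsets beyond the sequence ends, or past the point where
    the propagated mask empties, are absent.
    """

    source: Segment
    window: int
    masks: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class TemporalLink:
    """A temporal relationship between candidate segments of two frames."""

    a: NodeKey
    b: NodeKey
    confidence: float

    @property
    def span(self) -> int:
        return abs(self.a[0] - self.b[0])


def jaccard_confidence(T: np.ndarray, S: np.ndarray) -> float:
    """Overlap confidence ``|T ∩ S| / |T ∪ S|`` of two masks on one grid."""
    T = np.asarray(T, dtype=bool)
    S = np.asarray(S, dtype=bool)
    if T.shape != S.shape:
        raise ValueError("masks must share the same frame grid")
    union = np.count_nonzero(T | S)
    if union == 0:
        raise ValueError("Jaccard confidence of two empty masks is undefined")
    return np.count_nonzero(T & S) / union


def trace_segment(
    segment: Segment, n_frames: int, flow: FlowProvider, w: int = 5
) -> Trace:
    """Propagate a segment's mask ±w frames by iterative flow warping.

    Propagation in either direction stops early when the warped mask
    empties; the remaining offsets are left absent.
    """
    if w < 1:
        raise ValueError("window w must be >= 1")
    t0 = segment.frame_index
    if not 0 <= t0 < n_frames:
        raise ValueError("segment frame outside the sequence")
    trace = Trace(source=segment, window=w)
    for direction in (+1, -1):
        cur = segment.mask
        for step in range(1, w + 1):
            t_prev = t0 + direction * (step - 1)
            t_next = t0 + direction * step
            if not 0 <= t_next < n_frames:
                break
            cur = warp_mask(cur, flow.flow(t_prev, t_next))
            if not cur.any():
                break
            trace.masks[direction * step] = cur
    return trace


def intersect_trace(
    trace: Trace,
    candidates_by_frame: dict[int, list[Segment]],
    C: float = 0.5,
) -> list[TemporalLink]:
    """Links from a trace's source to overlapping candidates in the window.

    For each window frame the traced mask is intersected with every
    candidate there; a link is emitted iff the Jaccard confidence is
    strictly above ``C``. Because the trace covers up to ``w`` frames in
    each direction, links can skip frames where the object was missed.
    """
    if not 0 <= C < 1:
        raise ValueError("confidence threshold C must be in [0, 1)")
    src = trace.source
    links = []
    for offset, traced in sorted(trace.masks.items()):
        frame = src.frame_index + offset
        for cand in candidates_by_frame.get(frame, []):
            c = jaccard_confidence(traced, cand.mask)
            if c > C:
                links.append(TemporalLink(a=src.key, b=cand.key, confidence=c))
    return links


def build_connectivity_graph(
    candidates: list[Segment], links: list[TemporalLink]
) -> nx.Graph:
    """Undirected graph over candidate segments.

    Forward and backward links between the same pair collapse into one edge
    keeping the maximum confidence. Candidates without links stay as
    isolated nodes. Node keys are ``(frame_index, segment_id)``; the
    segment object is stored as the ``segment`` node attribute.
    """
    G = nx.Graph()
    for seg in candidates:
        G.add_node(seg.key, segment=seg)
    for link in links:
        if link.a not in G or link.b not in G:
            raise KeyError(f"link endpoint not among candidates: {link}")
        if link.a[0] == link.b[0]:
            raise ValueError("links must connect segments of different frames")
        if G.has_edge(link.a, link.b):
            G[link.a][link.b]["confidence"] = max(G[link.a][link.b]["confidence"], link.confidence)
        else:
            G.add_edge(link.a, link.b, confidence=link.confidence)
    return G


def extract_subgraphs(graph: nx.Graph) -> list[list[NodeKey]]:
    """Connected components, each sorted by (frame, id).

    Components are ordered deterministically by their earliest frame, ties
    broken by the lowest segment id in that frame.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda nodes: nodes[0])
    return comps


@dataclass
class SpatioTemporalSegment:
    """One track: per-frame merged masks of a connected component.

    ``masks`` maps frame index to the merged boolean mask. Frames inside
    the lifetime interval with no mask are tracking gaps. ``interpolated``
    flags frames whose masks were synthesized by gap filling.
    """

    track_id: int
    masks: dict[int, np.ndarray]
    interpolated: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("a track needs at least one frame")

    @property
    def frames_present(self) -> list[int]:
        return sorted(self.masks)

    @property
    def first(self) -> int:
        return min(self.masks)

    @property
    def last(self) -> int:
        return max(self.masks)

    @property
    def lifetime(self) -> int:
        return self.last - self.first + 1

    @property
    def gap_frames(self) -> list[int]:
        return [t for t in range(self.first, self.last + 1) if t not in self.masks]


def merge_subgraph(
    component: list[NodeKey], graph: nx.Graph, track_id: int = 0
) -> SpatioTemporalSegment:
    """Spatially merge a component's member segments frame by frame."""
    if not component:
        raise ValueError("component must be non-empty")
    masks: dict[int, np.ndarray] = {}
    for key in component:
        seg: Segment = graph.nodes[key]["segment"]
        t = seg.frame_index
        if t in masks:
            masks[t] = masks[t] | seg.mask
        else:
            masks[t] = seg.mask
    return SpatioTemporalSegment(track_id=track_id, masks=masks)


def track_candidates(
    candidates_by_frame: dict[int, list[Segment]],
    n_frames: int,
    flow: FlowProvider,
    w: int = 5,
    C: float = 0.5,
) -> tuple[list[SpatioTemporalSegment], nx.Graph]:
    """Full tracking stage: trace, intersect, graph, components, merge."""
    all_candidates = [s for segs in candidates_by_frame.values() for s in segs]
    links: list[TemporalLink] = []
    for seg in all_candidates:
        trace = trace_segment(seg, n_frames, flow, w=w)
        links.extend(intersect_trace(trace, candidates_by_frame, C=C))
    graph = build_connectivity_graph(all_candidates, links)
    tracks = [
        merge_subgraph(comp, graph, track_id=i)
        for i, comp in enumerate(extract_subgraphs(graph))
    ]
    return tracks, graph
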