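"""Gap interpolation for validated tracks.

Tracking links can span up to ``w`` frames, so a validated track may
contain gaps — frames inside its lifetime where the detection was missed
(noise, partial occlusion, segmentation failure). Gaps are closed by
propagating the temporally nearer flanking mask into the gap with the same
optical flow already used for tracing; exact mid-gap ties propagate from
the earlier flank. Interpolated frames are flagged so that later feature
computations can exclude them.
"""

from __future__ import annotations

from .flow import FlowProvider, warp_mask
from .tracking import SpatioTemporalSegment

__all__ = ["fill_gaps"]


def fill_gaps(track: SpatioTemporalSegment, flow: FlowProvider) -> SpatioTemporalSegment:
    """Close every tracking gap by flow-propagating the nearer flank.

    Returns a new track whose ``frames_present`` is the contiguous interval
    [first, last]; inserted frames are recorded in ``interpolated``. The
    operation is idempotent: a gap-free track is returned as a copy.
    """
    masks = dict(track.masks)
    interpolated = set(track.interpolated)
    present = sorted(track.masks)
    for gap in track.gap_frames:
        before = max(t for t in present if t < gap)
        after = min(t for t in present if t > gap)
        # nearer flank wins; exact ties propagate from the earlier flank
        if gap - before <= after - gap:
            start = before
        else:
            start = after
        cur = track.masks[start]
        step = 1 if gap > start else -1
        t = start
        while t != gap:
            cur = warp_mask(cur, flow.flow(t, t + step))
            t += step
        masks[gap] = cur
        interpolated.add(gap)
    return SpatioTemporalSegment(track_id=track.track_id, masks=masks, interpolated=interpolated)
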