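import numpy as np
import pytest

from wildtrack.flow import ConstantFlow, FieldFlow, ZeroFlow, warp_mask
from wildtrack.segmentation import Segment
from wildtrack.tracking import (
    SpatioTemporalSegment,
    TemporalLink,
    build_connectivity_graph,
    extract_subgraphs,
    intersect_trace,
    jaccard_confidence,
    merge_subgraph,
    trace_segment,
)

SHAPE = (40, 60)


def rect_mask(r0, r1, c0, c1, shape=SHAPE):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def make_segment(frame, seg_id, mask):
    rr, cc = np.nonzero(mask)
    r0, r1, c0, c1 = rr.min(), rr.max() + 1, cc.min(), cc.max() + 1
    return Segment(
        id=seg_id, frame_index=frame, area=int(mask.sum()),
        mean_color=np.zeros(3), shape=mask.shape,
        bbox=(int(r0), int(r1), int(c0), int(c1)), submask=mask[r0:r1, c0:c1],
    )


class TestJaccard:
    def test_identity_is_one(self):
        m = rect_mask(5, 10, 5, 10)
        assert jaccard_confidence(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert jaccard_confidence(rect_mask(0, 5, 0, 5), rect_mask(20, 25, 20, 25)) == 0.0

    def test_partial_overlap_fraction(self):
        # |T|=4, |S|=4, overlap 2 -> 2/6
        T = rect_mask(0, 1, 0, 4)
        S = rect_mask(0, 1, 2, 6)
        assert jaccard_confidence(T, S) == pytest.approx(2 / 6)

    def test_empty_union_is_an_error(self):
        empty = np.zeros(SHAPE, dtype=bool)
        with pytest.raises(ValueError):
            jaccard_confidence(empty, empty)

    def test_random_masks_match_set_arithmetic_oracle(self, rng):
        for _ in range(50):
            a = rng.random((12, 12)) < 0.4
            b = rng.random((12, 12)) < 0.4
            if not (a | b).any():
                continue
            sa = {(i, j) for i, j in zip(*np.nonzero(a))}
            sb = {(i, j) for i, j in zip(*np.nonzero(b))}
            expected = len(sa & sb) / len(sa | sb)
            assert jaccard_confidence(a, b) == pytest.approx(expected)


class TestTraceSegment:
    def test_zero_flow_reproduces_source(self):
        seg = make_segment(3, 0, rect_mask(10, 20, 10, 25))
        trace = trace_segment(seg, 10, ZeroFlow(SHAPE), w=3)
        assert set(trace.masks) == {-3, -2, -1, 1, 2, 3}
        for m in trace.masks.values():
            assert np.array_equal(m, seg.mask)

    def test_constant_flow_translates(self):
        seg = make_segment(3, 0, rect_mask(10, 20, 10, 25))
        trace = trace_segment(seg, 10, ConstantFlow(SHAPE, 3, 0), w=2)
        assert np.array_equal(trace.masks[2], rect_mask(16, 26, 10, 25))
        assert np.array_equal(trace.masks[-2], rect_mask(4, 14, 10, 25))

    def test_clipping_at_sequence_start(self):
        seg = make_segment(0, 0, rect_mask(10, 20, 10, 25))
        trace = trace_segment(seg, 10, ZeroFlow(SHAPE), w=2)
        assert set(trace.masks) == {1, 2}

    def test_clipping_at_frame_border(self):
        seg = make_segment(2, 0, rect_mask(30, 40, 0, 10))
        trace = trace_segment(seg, 10, ConstantFlow(SHAPE, 6, 0), w=2)
        assert np.array_equal(trace.masks[1], rect_mask(36, 40, 0, 10))

    def test_propagation_stops_when_mask_leaves_frame(self):
        seg = make_segment(2, 0, rect_mask(36, 40, 0, 10))
        trace = trace_segment(seg, 10, ConstantFlow(SHAPE, 20, 0), w=3)
        assert 1 not in trace.masks  # fully off-frame after one step

    def test_frame_outside_sequence_rejected(self):
        seg = make_segment(12, 0, rect_mask(0, 5, 0, 5))
        with pytest.raises(ValueError):
            trace_segment(seg, 10, ZeroFlow(SHAPE), w=2)


class TestIntersectTrace:
    def build_split_merge_scene(self):
        """A source blob that splits in t+1, merges in t+2, is absent at
        t-1, and reappears at t-2 — the canonical split/merge/gap layout."""
        src = make_segment(2, 0, rect_mask(10, 20, 10, 30))
        u = make_segment(3, 0, rect_mask(10, 20, 10, 19))
        v = make_segment(3, 1, rect_mask(10, 20, 29, 31))  # sliver, tiny overlap
        w_ = make_segment(4, 0, rect_mask(10, 20, 10, 30))
        k = make_segment(0, 0, rect_mask(10, 20, 10, 30))
        cands = {3: [u, v], 4: [w_], 0: [k], 1: []}
        return src, cands

    def test_split_merge_and_gap_links(self):
        src, cands = self.build_split_merge_scene()
        trace = trace_segment(src, 6, ZeroFlow(SHAPE), w=2)
        links = intersect_trace(trace, cands, C=0.3)
        linked = {l.b for l in links}
        assert (3, 0) in linked  # heavy-overlap split member u
        assert (3, 1) not in linked  # sliver v stays unlinked
        assert (4, 0) in linked  # merged segment w
        assert (0, 0) in linked  # gap at t-1 bridged by a span-2 link
        assert all(l.confidence > 0.3 for l in links)
        assert all(l.span <= 2 for l in links)

    def test_identical_candidate_gets_confidence_one(self):
        src = make_segment(1, 0, rect_mask(5, 15, 5, 15))
        cand = make_segment(2, 0, rect_mask(5, 15, 5, 15))
        trace = trace_segment(src, 4, ZeroFlow(SHAPE), w=1)
        links = intersect_trace(trace, {2: [cand]}, C=0.99)
        assert len(links) == 1 and links[0].confidence == 1.0

    def test_threshold_monotonicity(self, rng):
        segs = {}
        for t in range(4):
            masks = [rng.random(SHAPE) < 0.2 for _ in range(3)]
            segs[t] = [make_segment(t, i, m) for i, m in enumerate(masks) if m.any()]
        src = segs[1][0]
        trace = trace_segment(src, 4, ZeroFlow(SHAPE), w=2)
        loose = {(l.a, l.b) for l in intersect_trace(trace, segs, C=0.1)}
        strict = {(l.a, l.b) for l in intersect_trace(trace, segs, C=0.9)}
        assert strict <= loose

    def test_invalid_threshold(self):
        src = make_segment(0, 0, rect_mask(0, 5, 0, 5))
        trace = trace_segment(src, 3, ZeroFlow(SHAPE), w=1)
        with pytest.raises(ValueError):
            intersect_trace(trace, {}, C=1.0)


class TestConnectivityGraph:
    def test_no_links_gives_isolated_nodes(self):
        segs = [make_segment(t, 0, rect_mask(0, 5, 0, 5)) for t in range(3)]
        G = build_connectivity_graph(segs, [])
        assert G.number_of_nodes() == 3 and G.number_of_edges() == 0

    def test_forward_and_backward_links_collapse(self):
        a = make_segment(0, 0, rect_mask(0, 5, 0, 5))
        b = make_segment(1, 0, rect_mask(0, 5, 0, 5))
        links = [TemporalLink(a.key, b.key, 0.7), TemporalLink(b.key, a.key, 0.9)]
        G = build_connectivity_graph([a, b], links)
        assert G.number_of_edges() == 1
        assert G[a.key][b.key]["confidence"] == 0.9

    def test_split_merge_scene_contains_a_cycle(self):
        import networkx as nx

        s = make_segment(0, 0, rect_mask(10, 20, 10, 30))
        u = make_segment(1, 0, rect_mask(10, 20, 10, 20))
        v = make_segment(1, 1, rect_mask(10, 20, 20, 30))
        w_ = make_segment(2, 0, rect_mask(10, 20, 10, 30))
        links = [
            TemporalLink(s.key, u.key, 0.6),
            TemporalLink(s.key, v.key, 0.6),
            TemporalLink(u.key, w_.key, 0.6),
            TemporalLink(v.key, w_.key, 0.6),
        ]
        G = build_connectivity_graph([s, u, v, w_], links)
        assert len(nx.cycle_basis(G)) >= 1

    def test_dangling_endpoint_rejected(self):
        a = make_segment(0, 0, rect_mask(0, 5, 0, 5))
        with pytest.raises(KeyError):
            build_connectivity_graph([a], [TemporalLink(a.key, (1, 9), 0.8)])


def union_find_components(n_nodes, edges):
    """Independent oracle: plain union-find over integer nodes."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n_nodes):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


class TestSubgraphExtraction:
    def test_matches_union_find_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(1, 25))
            nodes = [make_segment(int(rng.integers(0, 6)), i, rect_mask(0, 2, 0, 2)) for i in range(n)]
            keys = [s.key for s in nodes]
            links = []
            edges_int = []
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.integers(0, n, 2)
                if nodes[i].frame_index == nodes[j].frame_index:
                    continue  # same-frame links are not allowed
                links.append(TemporalLink(keys[i], keys[j], 0.9))
                edges_int.append((int(i), int(j)))
            G = build_connectivity_graph(nodes, links)
            got = {frozenset(keys.index(k) for k in comp) for comp in extract_subgraphs(G)}
            assert got == set(union_find_components(n, edges_int))

    def test_two_tracks_and_two_isolated_nodes_give_four_components(self):
        # two chains plus two degree-0 nodes
        chain1 = [make_segment(t, 0, rect_mask(0, 5, 0, 5)) for t in range(3)]
        chain2 = [make_segment(t, 1, rect_mask(10, 15, 10, 15)) for t in range(3)]
        iso = [make_segment(0, 5, rect_mask(30, 32, 30, 32)), make_segment(2, 7, rect_mask(35, 38, 35, 38))]
        links = [TemporalLink(c[i].key, c[i + 1].key, 0.8) for c in (chain1, chain2) for i in range(2)]
        G = build_connectivity_graph(chain1 + chain2 + iso, links)
        comps = extract_subgraphs(G)
        assert len(comps) == 4

    def test_single_node_is_its_own_component(self):
        a = make_segment(0, 0, rect_mask(0, 5, 0, 5))
        assert extract_subgraphs(build_connectivity_graph([a], [])) == [[a.key]]


class TestMergeSubgraph:
    def test_single_frame_component(self):
        a = make_segment(4, 0, rect_mask(0, 5, 0, 5))
        G = build_connectivity_graph([a], [])
        track = merge_subgraph([a.key], G)
        assert track.lifetime == 1 and track.gap_frames == []

    def test_disjoint_masks_merge_additively(self):
        a = make_segment(2, 0, rect_mask(0, 5, 0, 5))
        b = make_segment(2, 1, rect_mask(10, 15, 10, 15))
        c = make_segment(3, 0, rect_mask(0, 5, 0, 5))
        links = [TemporalLink(a.key, c.key, 0.8), TemporalLink(b.key, c.key, 0.8)]
        G = build_connectivity_graph([a, b, c], links)
        track = merge_subgraph([a.key, b.key, c.key], G)
        assert int(track.masks[2].sum()) == a.area + b.area

    def test_gap_bookkeeping(self):
        segs = [make_segment(t, 0, rect_mask(0, 5, 0, 5)) for t in (3, 4, 6)]
        links = [TemporalLink(segs[0].key, segs[1].key, 0.8), TemporalLink(segs[1].key, segs[2].key, 0.8)]
        G = build_connectivity_graph(segs, links)
        track = merge_subgraph([s.key for s in segs], G)
        assert track.lifetime == 4
        assert track.gap_frames == [5]
        assert set(track.frames_present) == {3, 4, 6}


class TestSyntheticFlowInjection:
    def test_panning_blob_is_traced_onto_itself(self, sequence):
        cands = sequence.candidates_from_truth()
        seg = cands[5][0]
        trace = trace_segment(seg, len(sequence.frames), sequence.flow_provider(), w=2)
        for offset, traced in trace.masks.items():
            match = [s for s in cands[5 + offset] if s.id == seg.id]
            if match:
                assert jaccard_confidence(traced, match[0].mask) > 0.8
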