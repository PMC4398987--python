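"""Feature formulas checked against independent brute-force recomputation."""

import numpy as np
import pytest

from wildtrack.segmentation import Frame
from wildtrack.st_features import (
    EDGE_FILTERS,
    EdgeHistogram,
    duration,
    edge_density,
    edge_histogram,
    extract_features,
    instability,
    shape_change,
    texture_variation,
)
from wildtrack.tracking import SpatioTemporalSegment


def track_with_frames(frames, shape=(20, 20)):
    masks = {t: np.ones(shape, dtype=bool) for t in frames}
    return SpatioTemporalSegment(track_id=0, masks=masks)


# --- independent oracles (deliberately naive) ---------------------------


def oracle_shape_change(areas):
    return (max(areas) - min(areas)) / max(areas)


def oracle_edge_density(hist_list):
    total = 0.0
    for h in hist_list:
        for b in h:
            total += b
    return total / len(hist_list)


def oracle_texture_variation(hist_list):
    acc = 0.0
    for j in range(5):
        col = [h[j] for h in hist_list]
        acc += max(col) - min(col)
    return acc / 5.0


def oracle_edge_histogram(mask, gray, threshold):
    """Literal per-block loop over the bounding box."""
    rr, cc = np.nonzero(mask)
    r0, c0 = rr.min(), cc.min()
    h = (rr.max() + 1 - r0) // 2 * 2
    w = (cc.max() + 1 - c0) // 2 * 2
    counts = [0] * 5
    n_blocks = 0
    for i in range(r0, r0 + h, 2):
        for j in range(c0, c0 + w, 2):
            if not mask[i : i + 2, j : j + 2].all():
                continue
            n_blocks += 1
            block = gray[i : i + 2, j : j + 2].astype(float)
            resp = [abs((block * f).sum()) for f in EDGE_FILTERS]
            best = int(np.argmax(resp))
            if resp[best] >= threshold:
                counts[best] += 1
    if n_blocks == 0:
        return None
    return [c / n_blocks for c in counts]


# --- consistency features ----------------------------------------------


class TestConsistency:
    @pytest.mark.parametrize(
        "frames,expected_duration,expected_instability",
        [
            ([4], 1, 0.0),
            ([3, 4, 6], 4, 0.25),
            (list(range(25)), 25, 0.0),
            ([0, 9], 10, 0.8),
            ([0, 1, 2, 3, 4, 5, 6, 7], 8, 0.0),
        ],
    )
    def test_span_and_gap_fraction(self, frames, expected_duration, expected_instability):
        track = track_with_frames(frames)
        assert duration(track) == expected_duration
        assert instability(track) == pytest.approx(expected_instability)

    def test_present_mode_counts_detected_frames(self):
        track = track_with_frames([3, 4, 6])
        assert duration(track, mode="present") == 3

    def test_lifetime_ten_with_eight_present(self):
        track = track_with_frames([0, 1, 2, 3, 4, 5, 6, 7, 9])
        del track.masks[3]
        assert instability(track) == pytest.approx(0.2)


class TestShapeChange:
    @pytest.mark.parametrize(
        "areas,expected",
        [([100, 100, 100], 0.0), ([50, 100, 75], 0.5), ([42], 0.0)],
    )
    def test_examples(self, areas, expected):
        assert shape_change(areas) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            shape_change([10, 0, 5])

    def test_random_series_match_oracle_and_bounds(self, rng):
        for _ in range(50):
            areas = rng.integers(1, 1000, size=rng.integers(1, 20)).tolist()
            got = shape_change(areas)
            assert got == pytest.approx(oracle_shape_change(areas))
            assert 0.0 <= got <= 1.0

    def test_permutation_invariance(self, rng):
        areas = rng.integers(1, 500, size=12).tolist()
        assert shape_change(areas) == pytest.approx(shape_change(areas[::-1]))


class TestEdgeHistogram:
    def test_constant_region_has_zero_bins(self):
        mask = np.ones((10, 10), dtype=bool)
        gray = np.full((10, 10), 100.0)
        h = edge_histogram(mask, gray)
        assert np.allclose(h.bins, 0.0) and h.valid

    def test_vertical_step_edge_fills_vertical_bin(self):
        gray = np.zeros((8, 8))
        gray[:, 3:] = 200.0  # step inside the (2,3) column block
        mask = np.ones((8, 8), dtype=bool)
        h = edge_histogram(mask, gray)
        # hand application to the step block [[0,200],[0,200]]: vertical
        # |0-200+0-200| = 400 wins; horizontal 0; diagonals 200*sqrt(2);
        # non-directional |0-400-0+400| = 0.
        assert h.bins[0] == pytest.approx(1 / 4)  # one edge block of 4 kept columns pairs per row pair
        assert np.allclose(h.bins[[1, 2, 3, 4]], 0.0)

    def test_bin_sum_is_edge_block_fraction(self, rng):
        gray = rng.uniform(0, 255, (16, 16))
        mask = rng.random((16, 16)) < 0.8
        if not mask.any():
            mask[0, 0] = True
        h = edge_histogram(mask, gray)
        if h.valid:
            oracle = oracle_edge_histogram(mask, gray, 11.0)
            assert np.allclose(h.bins, oracle)
            assert h.bins.sum() <= 1.0 + 1e-12

    def test_no_complete_block_flags_invalid(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, :] = True  # a 1-pixel-high stripe holds no full 2x2 block
        h = edge_histogram(mask, np.zeros((6, 6)))
        assert not h.valid and np.allclose(h.bins, 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            edge_histogram(np.zeros((4, 4), dtype=bool), np.zeros((4, 4)))

    def test_random_masks_match_bruteforce_oracle(self, rng):
        for _ in range(50):
            gray = rng.uniform(0, 255, (14, 14))
            mask = rng.random((14, 14)) < 0.6
            if not mask.any():
                continue
            h = edge_histogram(mask, gray)
            oracle = oracle_edge_histogram(mask, gray, 11.0)
            if oracle is None:
                assert not h.valid
            else:
                assert np.allclose(h.bins, oracle)


class TestTemporalTextureFeatures:
    def hist(self, bins):
        return EdgeHistogram(bins=np.asarray(bins, dtype=float), n_blocks=10)

    def test_edge_density_examples(self):
        assert edge_density([self.hist([0, 0, 0, 0, 0])]) == 0.0
        assert edge_density([self.hist([0.1, 0.2, 0, 0, 0.1])]) == pytest.approx(0.4)
        two = [self.hist([0.4, 0, 0, 0, 0]), self.hist([0.2, 0.2, 0.1, 0.1, 0])]
        assert edge_density(two) == pytest.approx(0.5)

    def test_texture_variation_examples(self):
        same = [self.hist([0.1, 0, 0.2, 0, 0])] * 3
        assert texture_variation(same) == 0.0
        pair = [self.hist([0.1, 0, 0, 0, 0.5]), self.hist([0.2, 0, 0, 0, 0.1])]
        assert texture_variation(pair) == pytest.approx(0.1)
        assert texture_variation([self.hist([0.3, 0.1, 0, 0, 0])]) == 0.0

    def test_random_series_match_oracles_and_permutation_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 15))
            raw = rng.dirichlet(np.ones(6), size=n)[:, :5]  # bin sums <= 1
            hists = [self.hist(b) for b in raw]
            fed = edge_density(hists)
            ftv = texture_variation(hists)
            assert fed == pytest.approx(oracle_edge_density(raw.tolist()))
            assert ftv == pytest.approx(oracle_texture_variation(raw.tolist()))
            assert 0 <= fed <= 1 and 0 <= ftv <= 1
            perm = [hists[i] for i in rng.permutation(n)]
            assert edge_density(perm) == pytest.approx(fed)
            assert texture_variation(perm) == pytest.approx(ftv)


class TestExtractFeatures:
    def luv_frames(self, n, texture=0.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for t in range(n):
            pixels = np.zeros((24, 24, 3))
            pixels[..., 0] = 50.0 + rng.normal(0, texture, (24, 24)) if texture else 50.0
            frames.append(Frame(t, pixels, "LUV"))
        return frames

    def test_static_smooth_blob_has_null_features(self):
        frames = self.luv_frames(6)
        masks = {t: np.pad(np.ones((10, 10), bool), 7) for t in range(6)}
        track = SpatioTemporalSegment(0, masks)
        fv = extract_features(track, frames)
        assert fv.duration == 6
        assert fv.instability == 0.0
        assert fv.shape_change == 0.0
        assert fv.edge_density == 0.0
        assert fv.texture_variation == 0.0

    def test_flickering_track_has_high_instability(self):
        frames = self.luv_frames(10)
        masks = {t: np.pad(np.ones((6, 6), bool), 9) for t in (2, 9)}
        fv = extract_features(SpatioTemporalSegment(0, masks), frames)
        assert fv.duration == 8
        assert fv.instability == pytest.approx(0.75)

    def test_textured_blob_has_higher_edge_density_than_smooth(self):
        smooth = self.luv_frames(4)
        textured = self.luv_frames(4, texture=20.0, seed=3)
        masks = {t: np.pad(np.ones((12, 12), bool), 6) for t in range(4)}
        f_smooth = extract_features(SpatioTemporalSegment(0, dict(masks)), smooth)
        f_textured = extract_features(SpatioTemporalSegment(0, dict(masks)), textured)
        assert f_textured.edge_density > f_smooth.edge_density

    def test_interpolated_frames_are_excluded(self):
        frames = self.luv_frames(5)
        masks = {t: np.pad(np.ones((8, 8), bool), 8) for t in range(5)}
        masks[2] = np.pad(np.ones((16, 16), bool), 4)  # huge interpolated mask
        track = SpatioTemporalSegment(0, masks, interpolated={2})
        fv = extract_features(track, frames)
        assert fv.shape_change == 0.0  # the flagged frame does not distort areas
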