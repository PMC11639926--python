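import numpy as np
import pytest

import siribruise as sb
from siribruise.segmentation import GrayHistogram


def _hist(counts_dict, n_levels=256):
    counts = np.zeros(n_levels, dtype=np.int64)
    for level, n in counts_dict.items():
        counts[level] = n
    return GrayHistogram(counts=counts)


def _random_histograms(rng, n=120):
    """Mix of sparse and dense random histograms."""
    hists = []
    for _ in range(n):
        counts = np.zeros(256, dtype=np.int64)
        k = int(rng.integers(2, 40))
        levels = rng.choice(256, size=k, replace=False)
        counts[levels] = rng.integers(1, 500, size=k)
        hists.append(GrayHistogram(counts=counts))
    return hists


# ---------------------------------------------------------------- oracles


def _split_stats(counts, t):
    levels = np.arange(256)
    c0, c1 = counts[: t + 1], counts[t + 1 :]
    n = counts.sum()
    w0, w1 = c0.sum(), c1.sum()
    if w0 == 0 or w1 == 0:
        return None
    mu0 = (c0 * levels[: t + 1]).sum() / w0
    mu1 = (c1 * levels[t + 1 :]).sum() / w1
    var0 = (c0 * (levels[: t + 1] - mu0) ** 2).sum() / w0
    var1 = (c1 * (levels[t + 1 :] - mu1) ** 2).sum() / w1
    return w0 / n, w1 / n, mu0, mu1, var0, var1


def _brute_force_otsu(counts):
    best_t, best = None, -np.inf
    for t in range(256):
        stats = _split_stats(counts, t)
        if stats is None:
            continue
        p0, p1, mu0, mu1, _, _ = stats
        obj = p0 * p1 * (mu0 - mu1) ** 2
        if obj > best + 1e-12:
            best, best_t = obj, t
    return best_t


def _brute_force_within_class_minimizer(counts):
    best_t, best = None, np.inf
    for t in range(256):
        stats = _split_stats(counts, t)
        if stats is None:
            continue
        p0, p1, _, _, var0, var1 = stats
        obj = p0 * var0 + p1 * var1
        if obj < best - 1e-12:
            best, best_t = obj, t
    return best_t


def _brute_force_improved(counts):
    n = counts.sum()
    mu = (counts * np.arange(256)).sum() / n
    best_t, best = None, -np.inf
    for t in range(256):
        stats = _split_stats(counts, t)
        if stats is None:
            continue
        p0, p1, mu0, mu1, _, _ = stats
        obj = p0 * p1 * (mu0 - mu1) ** 2 + (mu0 - mu) ** 2 + (mu1 - mu) ** 2
        if obj > best + 1e-12:
            best, best_t = obj, t
    return best_t


# ------------------------------------------------------------------ tests


class TestMaskedHistogram:
    def test_constant_half_gray(self):
        img = np.full((8, 8), 0.5)
        hist = sb.masked_histogram(img, np.ones((8, 8), bool))
        assert hist.counts[128] == 64 and hist.counts.sum() == 64

    def test_black_and_white_split(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        hist = sb.masked_histogram(img, np.ones((8, 8), bool))
        assert hist.counts[0] == 32 and hist.counts[255] == 32

    def test_conserves_masked_pixel_count(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        mask = rng.uniform(0, 1, (16, 16)) > 0.4
        hist = sb.masked_histogram(img, mask)
        assert hist.n_pixels == mask.sum()

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sb.masked_histogram(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestClassSplit:
    def test_boundary_threshold_gives_single_class(self):
        hist = _hist({10: 5, 200: 5})
        split = sb.class_split(hist, 255)
        assert split.p1 == 0.0 and split.p0 == 1.0
        assert split.mu0 == pytest.approx(split.mu)
        assert np.isnan(split.mu1)

    def test_two_level_histogram(self):
        split = sb.class_split(_hist({50: 7, 200: 7}), 100)
        assert split.p0 == split.p1 == 0.5
        assert split.mu0 == 50 and split.mu1 == 200

    def test_global_mean_is_probability_weighted_class_mean(self, rng):
        for hist in _random_histograms(rng, n=20):
            for t in rng.integers(0, 256, size=5):
                split = sb.class_split(hist, int(t))
                if split.p0 > 0 and split.p1 > 0:
                    assert split.mu == pytest.approx(
                        split.p0 * split.mu0 + split.p1 * split.mu1, abs=1e-12
                    )


class TestOtsu:
    def test_two_level_tie_breaks_to_smallest(self):
        t, _ = sb.otsu_threshold(_hist({50: 9, 200: 9}))
        assert t == 50  # all T in [50, 199] tie

    def test_matches_bruteforce_on_handbuilt_histogram(self):
        hist = _hist({10: 30, 30: 50, 60: 5, 100: 80, 140: 60, 180: 20, 220: 40, 250: 10})
        t, _ = sb.otsu_threshold(hist)
        assert t == _brute_force_otsu(hist.counts)

    def test_matches_bruteforce_on_random_histograms(self, rng):
        for hist in _random_histograms(rng, n=30):
            t, _ = sb.otsu_threshold(hist)
            assert t == _brute_force_otsu(hist.counts)

    def test_between_class_maximizer_equals_within_class_minimizer(self, rng):
        for hist in _random_histograms(rng, n=30):
            assert _brute_force_otsu(hist.counts) == _brute_force_within_class_minimizer(
                hist.counts
            )

    def test_agrees_with_skimage_on_dense_histogram(self, rng):
        from skimage.filters import threshold_otsu

        img = rng.normal(0.35, 0.1, (64, 64)).clip(0, 1)
        img[:20] = rng.normal(0.8, 0.05, (20, 64)).clip(0, 1)
        hist = sb.masked_histogram(img, np.ones(img.shape, bool))
        t, _ = sb.otsu_threshold(hist)
        t_ref = threshold_otsu(hist=(hist.counts, np.arange(256)))
        assert t == int(t_ref)

    def test_shift_invariance(self):
        hist = _hist({20: 40, 60: 10, 120: 50})
        shifted = _hist({50: 40, 90: 10, 150: 50})
        assert sb.otsu_threshold(shifted)[0] == sb.otsu_threshold(hist)[0] + 30

    def test_single_level_degenerate(self):
        with pytest.raises(ValueError, match="occupied"):
            sb.otsu_threshold(_hist({100: 50}))


class TestImprovedOtsu:
    def test_objective_equals_closed_form(self, rng):
        # substituting mu = p0*mu0 + p1*mu1 gives (mu0-mu1)^2 * (1 - p0*p1)
        for hist in _random_histograms(rng, n=30):
            _, curve = sb.improved_otsu_threshold(hist)
            for t in range(256):
                stats = _split_stats(hist.counts, t)
                if stats is None:
                    assert np.isnan(curve[t])
                    continue
                p0, p1, mu0, mu1, _, _ = stats
                closed = (mu0 - mu1) ** 2 * (1 - p0 * p1)
                assert curve[t] == pytest.approx(closed, abs=1e-9, rel=1e-9)

    def test_matches_bruteforce_on_handbuilt_histogram(self):
        hist = _hist({0: 200, 35: 60, 120: 15, 200: 300, 230: 50})
        t, _ = sb.improved_otsu_threshold(hist)
        assert t == _brute_force_improved(hist.counts)

    def test_matches_bruteforce_on_random_histograms(self, rng):
        for hist in _random_histograms(rng, n=30):
            t, _ = sb.improved_otsu_threshold(hist)
            assert t == _brute_force_improved(hist.counts)

    def test_two_level_histogram_matches_otsu(self):
        hist = _hist({50: 9, 200: 9})
        assert sb.improved_otsu_threshold(hist)[0] == sb.otsu_threshold(hist)[0]


class TestApplyThreshold:
    def test_full_and_empty_boundaries(self, rng):
        img = rng.uniform(0.1, 0.9, (10, 10))
        mask = np.ones((10, 10), bool)
        full = sb.apply_threshold(img, mask, 255)
        assert full.bruise_mask.sum() == 100
        empty = sb.apply_threshold(img, mask, 0)
        assert empty.bruise_mask.sum() == 0  # no zero-level pixels

    def test_polarity_above(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        mask = np.ones((10, 10), bool)
        below = sb.apply_threshold(img, mask, 128, polarity="below")
        above = sb.apply_threshold(img, mask, 128, polarity="above")
        assert not (below.bruise_mask & above.bruise_mask).any()
        assert (below.bruise_mask | above.bruise_mask).all()

    def test_bruise_mask_confined_to_foreground(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        seg = sb.apply_threshold(img, mask, 255)
        assert not seg.bruise_mask[5:].any()


class TestGlobalThreshold:
    def test_consistent_with_otsu_at_same_threshold(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        mask = np.ones((16, 16), bool)
        hist = sb.masked_histogram(img, mask)
        t, curve = sb.otsu_threshold(hist)
        via_otsu = sb.apply_threshold(img, mask, t, method="otsu", objective_curve=curve)
        via_global = sb.global_threshold_segment(img, mask, t)
        np.testing.assert_array_equal(via_global.bruise_mask, via_otsu.bruise_mask)

    def test_mask_area_monotone_in_threshold(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        mask = np.ones((16, 16), bool)
        areas = [
            sb.global_threshold_segment(img, mask, t).bruise_mask.sum()
            for t in range(0, 256, 16)
        ]
        assert (np.diff(areas) >= 0).all()


def _bfs_components(mask, connectivity=8):
    """Independent flood-fill labeler."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


class TestRemoveSmallComponents:
    def _seg(self, mask):
        return sb.SegmentationResult(method="global", threshold=0, bruise_mask=mask)

    def test_empty_stays_empty(self):
        out = sb.remove_small_components(self._seg(np.zeros((8, 8), bool)), 50)
        assert not out.bruise_mask.any()

    def test_component_of_exactly_min_area_retained(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:5] = True  # area 6
        out = sb.remove_small_components(self._seg(mask), 6)
        assert out.bruise_mask.sum() == 6
        out = sb.remove_small_components(self._seg(mask), 7)
        assert out.bruise_mask.sum() == 0

    def test_survivors_validated_by_floodfill_oracle(self, rng):
        mask = rng.uniform(0, 1, (40, 40)) > 0.55
        out = sb.remove_small_components(self._seg(mask), 50)
        for comp in _bfs_components(out.bruise_mask):
            assert len(comp) >= 50
        # nothing with area >= 50 may be dropped
        kept = {pix for comp in _bfs_components(mask) if len(comp) >= 50 for pix in comp}
        assert kept == set(zip(*np.nonzero(out.bruise_mask)))

    def test_antitone_in_min_area(self, rng):
        mask = rng.uniform(0, 1, (30, 30)) > 0.5
        prev = None
        for min_area in (0, 5, 20, 80):
            out = sb.remove_small_components(self._seg(mask), min_area).bruise_mask
            if prev is not None:
                assert not (out & ~prev).any()  # larger min_area never adds pixels
            prev = out

    def test_connectivity_4_splits_diagonals(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = True  # diagonal pair
        assert sb.remove_small_components(self._seg(mask), 2, connectivity=8).n_pixels == 2
        assert sb.remove_small_components(self._seg(mask), 2, connectivity=4).n_pixels == 0


class TestClassifySample:
    def _seg(self, mask):
        return sb.SegmentationResult(method="iotsu", threshold=10, bruise_mask=mask)

    def test_empty_mask_is_normal(self):
        result = sb.classify_sample(self._seg(np.zeros((8, 8), bool)))
        assert result.label == "normal" and result.surviving_pixels == 0

    def test_any_pixels_mean_bruised(self):
        mask = np.zeros((8, 8), bool)
        mask[3:5, 3:6] = True
        result = sb.classify_sample(self._seg(mask))
        assert result.label == "bruised"
        assert result.surviving_pixels == 6
        assert len(result.components) == 1
        area, centroid = result.components[0]
        assert area == 6 and centroid == (3.5, 4.0)
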