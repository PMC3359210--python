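import numpy as np
import pytest

from entroseg import (
    binarize,
    criterion_curve,
    entropy_criterion,
    histogram,
    max_entropy_threshold,
    mode_filter,
    multistage_segment,
)
from conftest import make_three_population_image


def brute_force_criterion(p, j, variant="kapur"):
    """Independent scalar evaluation of the entropy criterion at one cut."""
    p = np.asarray(p, float)
    p = p / p.sum()
    a, b = p[: j + 1], p[j + 1 :]
    pa, pb = a.sum(), b.sum()
    if not (a > 0).any() or not (b > 0).any():
        return -np.inf
    ha = -sum(x * np.log(x) for x in a if x > 0)
    hb = -sum(x * np.log(x) for x in b if x > 0)
    if variant == "kapur":
        return np.log(pa) + ha / pa + np.log(pb) + hb / pb
    return -np.log(pa) - np.log(pb) - ha * pa - hb * pb


class TestHistogram:
    def test_two_value_image(self):
        h = histogram(np.array([[0, 0], [255, 255]]))
        assert h.probabilities[0] == 0.5
        assert h.probabilities[255] == 0.5
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.n_bins == 256

    def test_constant_image(self):
        h = histogram(np.full((3, 3), 7))
        assert h.probabilities[7] == 1.0

    def test_counts_conserve_pixels(self, rng):
        img = rng.integers(0, 256, (13, 17))
        assert histogram(img).counts.sum() == 13 * 17

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            histogram(np.empty((0, 3)))
        with pytest.raises(ValueError):
            histogram(np.array([[300]]))


class TestEntropyCriterion:
    def test_two_point_histogram_in_gap(self):
        """With single-bin classes both class entropies vanish; the
        criterion is constant (0) across the empty gap."""
        p = np.zeros(256)
        p[0] = p[255] = 0.5
        assert entropy_criterion(p, 100) == pytest.approx(0.0, abs=1e-12)
        assert entropy_criterion(p, 1) == entropy_criterion(p, 200)

    def test_degenerate_split_is_minus_inf(self):
        p = np.zeros(256)
        p[0] = p[255] = 0.5
        assert entropy_criterion(p, 255) == -np.inf

    def test_uniform_histogram_is_symmetric(self):
        curve = criterion_curve(np.ones(256))
        for j in range(255):
            assert curve[j] == pytest.approx(curve[254 - j], rel=1e-9)

    @pytest.mark.parametrize("variant", ["kapur", "printed"])
    def test_matches_brute_force_scan(self, variant, rng):
        """Vectorised curve equals independent per-cut evaluation."""
        for _ in range(20):
            counts = rng.integers(0, 50, 64)
            if np.count_nonzero(counts) < 2:
                continue
            curve = criterion_curve(counts, variant)
            for j in range(64):
                assert curve[j] == pytest.approx(
                    brute_force_criterion(counts, j, variant), rel=1e-9, abs=1e-12
                )


class TestMaxEntropyThreshold:
    def test_argmax_equals_brute_force_on_random_histograms(self, rng):
        """The selected cut-off maximises the criterion, smallest j on
        ties, over 100 random 64-bin histograms."""
        checked = 0
        while checked < 100:
            counts = rng.integers(0, 30, 64)
            if np.count_nonzero(counts) < 2:
                continue
            res = max_entropy_threshold(counts)
            brute = np.array([brute_force_criterion(counts, j) for j in range(64)])
            assert res.cutoff == int(np.argmax(brute))
            assert res.max_entropy == pytest.approx(brute.max(), rel=1e-9)
            checked += 1

    def test_bimodal_tie_break_to_smallest(self):
        counts = np.zeros(256)
        counts[50] = counts[200] = 10
        res = max_entropy_threshold(counts)
        assert res.cutoff == 50
        assert not res.degenerate

    def test_separates_bounded_blob_modes_exactly(self, rng):
        """Dark blob pixels with bounded support are recovered exactly;
        the cut lands between the two populations."""
        img = rng.integers(215, 226, (100, 100))
        img[:50, :50] = rng.integers(25, 36, (50, 50))
        res = max_entropy_threshold(histogram(img))
        assert 35 <= res.cutoff < 215
        truth = np.full((100, 100), 255, np.uint8)
        truth[:50, :50] = 0
        np.testing.assert_array_equal(binarize(img, res.cutoff), truth)

    def test_constant_image_is_degenerate(self):
        res = max_entropy_threshold(histogram(np.full((4, 4), 99)))
        assert res.degenerate
        assert res.cutoff == 99

    def test_restricted_range_renormalises(self, rng):
        counts = rng.integers(1, 20, 256)
        res = max_entropy_threshold(counts, lo=64, hi=127)
        assert 64 <= res.cutoff <= 127
        sub = max_entropy_threshold(counts[64:128])
        assert res.cutoff == 64 + sub.cutoff

    def test_padding_empty_bins_does_not_move_cutoff(self, rng):
        counts = np.zeros(256)
        counts[10:40] = rng.integers(1, 20, 30)
        base = max_entropy_threshold(counts[:64])
        padded = max_entropy_threshold(counts)
        assert base.cutoff == padded.cutoff

    def test_empty_range_raises(self):
        counts = np.zeros(256)
        counts[5] = 3
        with pytest.raises(ValueError):
            max_entropy_threshold(counts, lo=100, hi=200)


class TestBinarize:
    def test_direct_application(self):
        np.testing.assert_array_equal(
            binarize(np.array([[10, 200]]), 100), np.array([[0, 255]], dtype=np.uint8)
        )

    def test_extreme_cutoffs(self):
        ch = np.array([[5, 250]])
        assert np.all(binarize(ch, 255) == 0)
        assert np.all(binarize(ch, 0) == 255)

    def test_output_coding_partitions_pixels(self, rng):
        ch = rng.integers(0, 256, (20, 20))
        mask = binarize(ch, 128)
        assert set(np.unique(mask)) <= {0, 255}
        assert (mask == 0).sum() + (mask == 255).sum() == 400


class TestMultistageSegment:
    def test_recovers_nuclei_from_three_populations(self):
        """Nuclei (~40) inside cytoplasm rings (~140) on bright
        background (~240), sigma 8: Dice >= 0.95 before mode filtering."""
        img, truth = make_three_population_image(seed=1)
        res = multistage_segment(img)
        inter = np.sum((res.mask == 0) & (truth == 0))
        dice = 2 * inter / ((res.mask == 0).sum() + (truth == 0).sum())
        assert dice >= 0.95

    def test_layers_partition_image(self):
        img, _ = make_three_population_image(seed=2)
        res = multistage_segment(img)
        assert res.layers.min() >= 0
        assert res.layers.max() <= len(res.boundaries)
        counts = np.bincount(res.layers.ravel(), minlength=len(res.boundaries) + 1)
        assert counts.sum() == img.size
        np.testing.assert_array_equal(counts, res.layer_counts)

    def test_constant_image_flagged_empty(self):
        res = multistage_segment(np.full((8, 8), 120))
        assert res.degenerate
        assert np.all(res.mask == 255)

    def test_collapsed_range_equals_single_stage(self, rng):
        """All values in [0, 63]: the multistage result reduces to the
        single-stage threshold of that sub-range."""
        vals = np.concatenate(
            [
                np.clip(np.rint(rng.normal(10, 3, 2000)), 0, 63),
                np.clip(np.rint(rng.normal(50, 3, 3000)), 0, 63),
            ]
        ).astype(int)
        img = rng.permutation(vals).reshape(50, 100)
        res = multistage_segment(img)
        single = max_entropy_threshold(histogram(img), 0, 63)
        np.testing.assert_array_equal(res.mask, binarize(img, single.cutoff))

    def test_bright_foreground_polarity_flag(self):
        img, truth = make_three_population_image(seed=3)
        dark = multistage_segment(img, foreground="dark")
        bright = multistage_segment(img, foreground="bright")
        np.testing.assert_array_equal(
            (dark.mask == 0), (bright.mask == 255)
        )


def brute_force_mode_filter(mask, radius, tie="foreground"):
    h, w = mask.shape
    out = np.empty_like(mask)
    for y in range(h):
        for x in range(w):
            win = mask[
                max(0, y - radius) : y + radius + 1, max(0, x - radius) : x + radius + 1
            ]
            fg = int((win == 0).sum())
            bg = win.size - fg
            if tie == "foreground":
                out[y, x] = 0 if fg >= bg else 255
            else:
                out[y, x] = 0 if fg > bg else 255
    return out


class TestModeFilter:
    def test_isolated_pixel_removed(self):
        mask = np.full((15, 15), 255, np.uint8)
        mask[7, 7] = 0
        assert np.all(mode_filter(mask, radius=3) == 255)

    def test_solid_square_retained_including_corners(self):
        mask = np.zeros((20, 20), np.uint8)
        assert np.all(mode_filter(mask, radius=3) == 0)

    @pytest.mark.parametrize("tie", ["foreground", "background"])
    def test_equals_brute_force_vote_count(self, tie, rng):
        for _ in range(5):
            mask = (rng.random((24, 24)) < 0.5).astype(np.uint8) * 255
            np.testing.assert_array_equal(
                mode_filter(mask, radius=3, tie=tie),
                brute_force_mode_filter(mask, 3, tie),
            )

    def test_checkerboard_matches_oracle(self):
        yy, xx = np.mgrid[0:8, 0:8]
        mask = (((yy + xx) % 2) * 255).astype(np.uint8)
        np.testing.assert_array_equal(
            mode_filter(mask, radius=3), brute_force_mode_filter(mask, 3)
        )

    def test_idempotent_on_locally_homogeneous_masks(self):
        """A half-plane split has a clear window majority everywhere, so
        it is a fixed point of the filter; reapplying changes nothing."""
        mask = np.full((30, 30), 255, np.uint8)
        mask[:, :15] = 0
        once = mode_filter(mask, radius=2)
        np.testing.assert_array_equal(once, mask)
        np.testing.assert_array_equal(mode_filter(once, radius=2), once)

    def test_rejects_non_binary_and_bad_radius(self):
        with pytest.raises(ValueError):
            mode_filter(np.array([[0, 17]], dtype=np.uint8))
        with pytest.raises(ValueError):
            mode_filter(np.zeros((3, 3), np.uint8), radius=0)
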