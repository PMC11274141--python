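import numpy as np
import pytest

from bitewing import (BoundingBox, ParameterError, PhantomSpec, SegmentationError,
                      SegmentConfig, ToothCrop, cuts_to_boxes, find_gap_cuts,
                      find_jaw_split, generate_bitewing, halve_crop,
                      projection_profile, segment_bitewing)
from bitewing.segmentation import ProjectionProfile


class TestProjectionProfile:
    def test_all_zero_image_gives_all_zero_profile(self):
        for axis in ("horizontal", "vertical"):
            assert not projection_profile(np.zeros((6, 8), np.uint8), axis).values.any()

    def test_single_white_column_shows_up_in_the_vertical_profile(self):
        img = np.zeros((10, 8), np.uint8)
        img[:, 3] = 255
        vp = projection_profile(img, "vertical")
        assert vp.values[3] == 255 * 10
        assert vp.values.sum() == 255 * 10

    def test_matches_double_loop_summation(self, random_gray):
        img = random_gray(8, 8)
        hp = projection_profile(img, "horizontal").values
        vp = projection_profile(img, "vertical").values
        for i in range(8):
            assert hp[i] == sum(int(img[i, j]) for j in range(8))
            assert vp[i] == sum(int(img[j, i]) for j in range(8))


class TestJawSplit:
    def make(self, values):
        return ProjectionProfile("horizontal", np.asarray(values), (len(values), 1))

    def test_unique_interior_minimum(self):
        values = np.full(80, 1000)
        values[40] = 5
        assert find_jaw_split(self.make(values)) == 40

    def test_plateau_resolves_to_the_midmost_row(self):
        values = np.full(80, 1000)
        values[38:43] = 5
        assert find_jaw_split(self.make(values)) == 40

    def test_search_ignores_dark_borders(self):
        values = np.full(100, 1000)
        values[:5] = 0          # dark frame border, outside the central band
        values[60] = 10
        assert find_jaw_split(self.make(values)) == 60

    def test_noiseless_phantom_split_is_recovered(self, quiet_phantom):
        img, truth = quiet_phantom
        hp = projection_profile(img, "horizontal")
        assert abs(find_jaw_split(hp) - truth.jaw_split_row) <= 5

    def test_vertical_profile_rejected(self):
        vp = ProjectionProfile("vertical", np.zeros(4), (3, 4))
        with pytest.raises(ParameterError):
            find_jaw_split(vp)


class TestGapCuts:
    def make(self, values):
        return ProjectionProfile("vertical", np.asarray(values), (1, len(values)))

    def test_single_valley_collapses_to_its_center(self):
        cuts = find_gap_cuts(self.make([900, 900, 0, 0, 0, 900, 900]), 400)
        assert cuts == [3]

    def test_no_subthreshold_run_gives_empty_list(self):
        assert find_gap_cuts(self.make([900] * 7), 400) == []

    def test_two_valleys_give_two_increasing_cuts(self):
        vals = [900, 900, 0, 0, 900, 900, 10, 10, 10, 900]
        cuts = find_gap_cuts(self.make(vals), 400)
        assert cuts == [2, 7]
        assert cuts == sorted(cuts)

    def test_border_touching_valleys_are_discarded(self):
        vals = [0, 0, 900, 10, 900, 0]
        assert find_gap_cuts(self.make(vals), 400) == [3]


class TestCutsToBoxes:
    def test_margin_expansion_matches_the_arithmetic(self):
        boxes = cuts_to_boxes([100, 200], (0, 50), margin=50, image_width=300)
        assert [(b.x0, b.x1) for b in boxes] == [(0, 150), (50, 250), (150, 300)]
        assert all((b.y0, b.y1) == (0, 50) for b in boxes)

    def test_no_cuts_gives_one_full_width_box(self):
        boxes = cuts_to_boxes([], (10, 20), margin=50, image_width=300)
        assert [(b.x0, b.x1) for b in boxes] == [(0, 300)]

    def test_zero_margin_partitions_the_width_exactly(self):
        boxes = cuts_to_boxes([80, 160, 240], (0, 10), margin=0, image_width=320)
        spans = [(b.x0, b.x1) for b in boxes]
        assert spans == [(0, 80), (80, 160), (160, 240), (240, 320)]

    def test_non_increasing_cuts_rejected(self):
        with pytest.raises(ParameterError):
            cuts_to_boxes([200, 100], (0, 10), 50, 300)


class TestHalveCrop:
    def crop(self, w):
        img = np.arange(4 * w, dtype=np.uint8).reshape(4, w) % 251
        return ToothCrop(img, BoundingBox(10, 0, 10 + w, 4), "upper", "whole")

    @pytest.mark.parametrize("w,expected", [(100, (50, 50)), (101, (50, 51))])
    def test_floor_halving_widths(self, w, expected):
        left, right = halve_crop(self.crop(w))
        assert (left.image.shape[1], right.image.shape[1]) == expected
        assert (left.side, right.side) == ("left", "right")

    def test_concatenating_halves_restores_the_crop(self):
        crop = self.crop(37)
        left, right = halve_crop(crop)
        assert np.array_equal(np.hstack([left.image, right.image]), crop.image)
        assert left.source_box.x1 == right.source_box.x0

    def test_width_below_two_rejected(self):
        with pytest.raises(ParameterError):
            halve_crop(self.crop(1))


class TestSegmentBitewing:
    def test_defaults_carry_the_documented_thresholds(self):
        cfg = SegmentConfig()
        assert cfg.binarize_threshold == 170
        assert cfg.valley_threshold == 400
        assert cfg.margin == 50

    def test_phantom_yields_four_crops_per_tooth_pair(self, quiet_phantom):
        img, truth = quiet_phantom
        crops = segment_bitewing(img)
        n = sum(1 for j in truth.jaw_of_box if j == "upper")
        assert len(crops) == 4 * n
        assert {(c.jaw, c.side) for c in crops} == {
            (j, s) for j in ("upper", "lower") for s in ("left", "right")}

    def test_crops_come_from_the_unfiltered_original(self, quiet_phantom):
        img, _ = quiet_phantom
        for crop in segment_bitewing(img):
            b = crop.source_box
            assert np.array_equal(crop.image, img[b.y0:b.y1, b.x0:b.x1])

    def test_blank_image_fails_at_the_gap_stage(self):
        with pytest.raises(SegmentationError) as err:
            segment_bitewing(np.zeros((100, 100), np.uint8))
        assert err.value.stage == "gap_cuts"

    def test_whole_crop_mode_skips_halving(self, quiet_phantom):
        img, truth = quiet_phantom
        crops = segment_bitewing(img, SegmentConfig(halve=False))
        assert len(crops) == len(truth.tooth_boxes)
        assert all(c.side == "whole" for c in crops)

    def test_moderate_noise_phantom_recovers_all_teeth(self):
        spec = PhantomSpec(teeth_per_jaw=7, noise_sigma=8.0,
                           calculus_probability=0.0, seed=77)
        img, _ = generate_bitewing(spec)
        assert len(segment_bitewing(img)) == 4 * 7
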