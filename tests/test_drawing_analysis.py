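"""Pen detection, clipping, gap filling, ratios and overlays."""

import numpy as np
import pytest

from paindraw import (
    BodyMask,
    InputError,
    PaintMask,
    ReferenceImage,
    SyntheticSpec,
    analyze_drawing,
    clip_to_body,
    complementary_overlay,
    detect_painted_pixels,
    pain_extent,
    simulate_drawing,
    smart_fill,
)
from oracles import fill_holes_bruteforce


def _white(h, w):
    return ReferenceImage(np.full((h, w, 3), 255, dtype=np.uint8))


def _mask_from(body):
    return BodyMask(body=body, front=np.zeros_like(body),
                    back=np.zeros_like(body),
                    total_body_pixels=int(body.sum()))


def _paint(mask_bool, pen=(255, 0, 0)):
    return PaintMask(painted=mask_bool, pen_color=pen,
                     painted_pixels=int(mask_bool.sum()))


class TestDetect:
    def test_unchanged_drawing_has_no_painted_pixels(self):
        ref = _white(8, 8)
        paint = detect_painted_pixels(_white(8, 8), ref)
        assert paint.painted_pixels == 0
        assert paint.pen_color is None

    def test_red_pixels_are_detected_with_modal_pen_color(self):
        ref = _white(8, 8)
        px = ref.pixels.copy()
        px[0, 0:5] = (255, 0, 0)
        paint = detect_painted_pixels(ReferenceImage(px), ref)
        assert paint.painted_pixels == 5
        assert paint.pen_color == (255, 0, 0)

    @pytest.mark.parametrize("color", [(0, 0, 0), (20, 20, 20),
                                       (250, 250, 250), (128, 128, 128)])
    def test_black_white_and_gray_never_count(self, color):
        # black and white are the template's own colors; grays are the
        # antialiasing residue the detector must ignore
        ref = _white(8, 8)
        px = ref.pixels.copy()
        px[2, 2] = color
        assert detect_painted_pixels(ReferenceImage(px), ref)\
            .painted_pixels == 0

    def test_pen_over_black_outline_counts(self):
        ref = _white(8, 8)
        rpx = ref.pixels.copy()
        rpx[4, 4] = 0
        ref = ReferenceImage(rpx)
        px = rpx.copy()
        px[4, 4] = (30, 160, 220)
        assert detect_painted_pixels(ReferenceImage(px), ref)\
            .painted_pixels == 1

    def test_dimension_mismatch_names_both_sizes(self):
        with pytest.raises(InputError, match=r"6x6.*8x8"):
            detect_painted_pixels(_white(6, 6), _white(8, 8))


class TestClipAndExtent:
    def test_half_inside_half_outside_keeps_inside_only(self):
        body = np.zeros((10, 10), dtype=bool)
        body[3:7, 0:4] = True  # 16-px body
        painted = np.zeros((10, 10), dtype=bool)
        painted[3:6, 2:6] = True  # 12 px: 6 inside, 6 outside
        clipped = clip_to_body(_paint(painted), _mask_from(body))
        assert clipped.painted_pixels == 6
        assert (clipped.painted <= body).all()

    def test_all_outside_clips_to_zero(self):
        body = np.zeros((6, 6), dtype=bool)
        body[0:2, 0:2] = True
        painted = np.zeros((6, 6), dtype=bool)
        painted[4:6, 4:6] = True
        assert clip_to_body(_paint(painted), _mask_from(body))\
            .painted_pixels == 0

    def test_subset_paint_is_unchanged(self):
        body = np.ones((5, 5), dtype=bool)
        painted = np.zeros((5, 5), dtype=bool)
        painted[1:3, 1:3] = True
        clipped = clip_to_body(_paint(painted), _mask_from(body))
        assert np.array_equal(clipped.painted, painted)

    @pytest.mark.parametrize("painted,total,expected", [
        (0, 1000, 0.0), (1000, 1000, 100.0), (40, 200, 20.0),
    ])
    def test_pain_extent_arithmetic(self, painted, total, expected):
        body = np.zeros((40, 40), dtype=bool)
        body.ravel()[:total] = True
        p = np.zeros((40, 40), dtype=bool)
        p.ravel()[:painted] = True
        assert pain_extent(_paint(p), _mask_from(body)) == expected


class TestSmartFill:
    def test_enclosed_hole_is_filled(self):
        body = np.ones((9, 9), dtype=bool)
        painted = np.zeros((9, 9), dtype=bool)
        painted[2:7, 2:7] = True
        painted[3:6, 3:6] = False  # 3x3 hole inside a 1-px ring
        filled = smart_fill(_paint(painted), _mask_from(body))
        assert filled.painted_pixels == 25
        assert filled.painted[4, 4]

    def test_open_c_shape_is_unchanged(self):
        body = np.ones((9, 9), dtype=bool)
        painted = np.zeros((9, 9), dtype=bool)
        painted[2:7, 2:7] = True
        painted[3:6, 3:6] = False
        painted[4, 6] = False  # break the ring: gap reaches the border
        filled = smart_fill(_paint(painted), _mask_from(body))
        assert np.array_equal(filled.painted, painted)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_hole_filling(self, seed):
        rng = np.random.default_rng(seed)
        h, w = (int(v) for v in rng.integers(4, 33, size=2))
        painted = rng.random((h, w)) < 0.45
        body = np.ones((h, w), dtype=bool)
        filled = smart_fill(_paint(painted), _mask_from(body))
        assert np.array_equal(filled.painted, fill_holes_bruteforce(painted))

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_and_idempotent(self, seed):
        rng = np.random.default_rng(100 + seed)
        painted = rng.random((24, 24)) < 0.4
        body = rng.random((24, 24)) < 0.9
        paint = clip_to_body(_paint(painted), _mask_from(body))
        once = smart_fill(paint, _mask_from(body))
        assert (paint.painted <= once.painted).all()  # never shrinks
        twice = smart_fill(once, _mask_from(body))
        assert np.array_equal(once.painted, twice.painted)


class TestOverlay:
    def test_complement_of_red_is_cyan(self):
        drawing = _white(6, 6)
        px = drawing.pixels.copy()
        px[1, 1:4] = (255, 0, 0)
        drawing = ReferenceImage(px)
        painted = np.zeros((6, 6), dtype=bool)
        painted[1, 1:4] = True
        overlay = complementary_overlay(drawing, _paint(painted))
        assert (overlay[1, 1:4] == (0, 255, 255)).all()

    def test_arbitrary_pen_complement(self):
        drawing = _white(4, 4)
        painted = np.zeros((4, 4), dtype=bool)
        painted[0, 0] = True
        overlay = complementary_overlay(
            drawing, _paint(painted, pen=(10, 200, 30)))
        assert tuple(overlay[0, 0]) == (245, 55, 225)

    def test_empty_paint_is_identity(self):
        drawing = _white(5, 5)
        empty = PaintMask(painted=np.zeros((5, 5), dtype=bool),
                          pen_color=None, painted_pixels=0)
        assert np.array_equal(complementary_overlay(drawing, empty),
                              drawing.pixels)

    def test_recolored_count_equals_painted_and_rest_untouched(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        drawing = ReferenceImage(px.copy())
        painted = rng.random((12, 12)) < 0.3
        overlay = complementary_overlay(drawing, _paint(painted))
        changed = (overlay != px).any(axis=2)
        assert (overlay[painted] == (0, 255, 255)).all()
        assert changed.sum() <= painted.sum()
        assert np.array_equal(overlay[~painted], px[~painted])


class TestAnalyzeDrawing:
    def _save(self, tmp_path, name, image):
        from PIL import Image
        p = tmp_path / name
        Image.fromarray(image.pixels).save(p)
        return p

    def test_exact_fraction_recovery(self, tmp_path, ref, body_mask):
        spec = SyntheticSpec(width=ref.width, height=ref.height,
                             target_fraction=0.25, seed=9)
        drawing, truth = simulate_drawing(ref, body_mask, spec)
        path = self._save(tmp_path, "quarter.png", drawing)
        result, paint = analyze_drawing(path, ref, body_mask)
        expected = 100.0 * truth.painted_pixels / body_mask.total_body_pixels
        assert result.ratio_percent == expected
        assert result.filename == "quarter.png"
        assert np.array_equal(paint.painted, truth.painted)

    def test_out_of_body_leaks_do_not_change_ratio(self, tmp_path, ref,
                                                   body_mask):
        base = SyntheticSpec(width=ref.width, height=ref.height,
                             target_fraction=0.2, seed=4)
        leaky = SyntheticSpec(width=ref.width, height=ref.height,
                              target_fraction=0.2, seed=4, leak_pixels=500)
        d0, _ = simulate_drawing(ref, body_mask, base)
        d1, _ = simulate_drawing(ref, body_mask, leaky)
        r0, _ = analyze_drawing(self._save(tmp_path, "a.png", d0),
                                ref, body_mask)
        r1, _ = analyze_drawing(self._save(tmp_path, "b.png", d1),
                                ref, body_mask)
        assert r0.ratio_percent == r1.ratio_percent

    def test_smart_fill_strictly_increases_ratio_of_ring(self, tmp_path,
                                                         ref, body_mask):
        hole = self._hole_box(body_mask)
        spec = SyntheticSpec(width=ref.width, height=ref.height,
                             target_fraction=0.25, seed=9, hole_spec=[hole])
        drawing, truth = simulate_drawing(ref, body_mask, spec)
        path = self._save(tmp_path, "ring.png", drawing)
        plain, _ = analyze_drawing(path, ref, body_mask, smart=False)
        smart, _ = analyze_drawing(path, ref, body_mask, smart=True)
        assert smart.ratio_percent > plain.ratio_percent
        assert smart.ratio_percent == \
            100.0 * truth.painted_pixels / body_mask.total_body_pixels

    @staticmethod
    def _hole_box(body_mask):
        # a 3x3 box centered deep inside the largest body run
        from scipy import ndimage
        eroded = ndimage.binary_erosion(body_mask.body, iterations=4)
        y, x = np.argwhere(eroded)[0]
        return (int(x) - 1, int(y) - 1, 3, 3)
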