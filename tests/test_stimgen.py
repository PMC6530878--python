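"""Stimulus generator: geometry oracles, symmetry and determinism."""

import numpy as np
import pytest
from skimage.measure import label

from crowdbench import (CATEGORIES, FlankerSpec, SizingError, StimulusSpec,
                        VernierGeometry, bouma_window, build_database, compose,
                        render_flankers, render_vernier)

CANVAS = (160, 560)


def _vernier(offset=2, direction="left", bar_length=20, bar_width=2, gap=2):
    return VernierGeometry(bar_length, bar_width, gap, offset, direction)


class TestRenderVernier:
    def test_zero_offset_left_right_identical(self):
        left = render_vernier(_vernier(offset=0, direction="left"), CANVAS)
        right = render_vernier(_vernier(offset=0, direction="right"), CANVAS)
        assert np.array_equal(left.pixels, right.pixels)

    def test_pixel_count_two_bars(self):
        img = render_vernier(_vernier(), CANVAS)
        # two bars of bar_length x bar_width each
        assert int((img.pixels > 0).sum()) == 2 * 20 * 2

    def test_binary_image(self):
        img = render_vernier(_vernier(), CANVAS)
        assert set(np.unique(img.pixels)) == {0.0, 1.0}

    def test_mirror_reflection(self):
        left = render_vernier(_vernier(direction="left"), CANVAS)
        right = render_vernier(_vernier(direction="right"), CANVAS)
        assert np.array_equal(np.fliplr(right.pixels), left.pixels)

    def test_oversized_geometry_rejected(self):
        with pytest.raises(SizingError):
            render_vernier(_vernier(bar_length=200), (100, 100))

    @pytest.mark.parametrize("kwargs", [
        {"bar_length": 0}, {"bar_width": 0}, {"offset": -1}, {"gap": -1},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            _vernier(**kwargs)


def _spec(shape="square", count=7, size=48, spacing=56, **kw):
    return StimulusSpec(category="squares", vernier=_vernier(),
                        flankers=FlankerSpec(shape=shape, size=size,
                                             count=count, spacing=spacing, **kw),
                        canvas=CANVAS, px_per_deg=32)


class TestRenderFlankers:
    def test_zero_count_blank(self):
        img = render_flankers(_spec(count=0))
        assert not img.pixels.any()

    def test_seven_squares_seven_components(self):
        img = render_flankers(_spec(count=7))
        assert label(img.pixels > 0, connectivity=2).max() == 7

    def test_grid_symmetric_about_midline(self):
        spec = StimulusSpec(category="patternStars", vernier=_vernier(),
                            flankers=FlankerSpec(shape="star", size=48,
                                                 count=21, spacing=56,
                                                 layout="grid3x7", mix="square"),
                            canvas=CANVAS, px_per_deg=32)
        img = render_flankers(spec)
        assert np.array_equal(img.pixels, np.fliplr(img.pixels))

    def test_overlapping_flankers_rejected(self):
        with pytest.raises(SizingError):
            render_flankers(_spec(count=3, spacing=40))

    def test_row_count_invariant(self):
        with pytest.raises(ValueError):
            FlankerSpec(shape="square", size=48, count=2, spacing=56)


class TestCompose:
    def test_identity_with_zeros(self):
        v = render_vernier(_vernier(), CANVAS)
        f = render_flankers(_spec(count=0))
        assert np.array_equal(compose(v, f).pixels, v.pixels)
        assert np.array_equal(compose(f, v).pixels, v.pixels)

    def test_nonzero_count_is_set_union(self):
        v = render_vernier(_vernier(), CANVAS)
        f = render_flankers(_spec(count=1))
        union = (v.pixels > 0) | (f.pixels > 0)
        assert int((compose(v, f).pixels > 0).sum()) == int(union.sum())

    def test_shape_mismatch_rejected(self):
        v = render_vernier(_vernier(), CANVAS)
        f = render_flankers(StimulusSpec(category="squares", vernier=_vernier(),
                                         flankers=FlankerSpec("square", 48, 0, 56),
                                         canvas=(128, 512), px_per_deg=32))
        with pytest.raises(ValueError):
            compose(v, f)


class TestDatabase:
    def test_forty_conditions_eleven_categories(self, db):
        assert len(db.entries) == 40
        assert len(db.categories()) == 11
        assert set(db.categories()) == set(CATEGORIES)

    def test_every_category_has_triplet(self, db):
        for cat in db.categories():
            alone, one, many = db.triplet_ids(cat)
            assert alone.endswith("/0")

    def test_mirror_property_symmetric_conditions(self, db):
        for m in db.manifest:
            if not m["symmetric"]:
                continue
            left, right = db.condition(m["condition_id"])
            assert np.array_equal(np.fliplr(left.pixels), right.pixels), \
                m["condition_id"]

    def test_monotone_ink_in_flanker_count(self, db):
        for cat in db.categories():
            inks = [int((db.condition(c)[0].pixels > 0).sum())
                    for c in db.triplet_ids(cat)]
            assert inks[0] < inks[1] < inks[2], cat

    def test_build_deterministic(self, db, config):
        again = build_database(config)
        for cond_id, (left, right) in db.entries.items():
            assert np.array_equal(left.pixels, again.condition(cond_id)[0].pixels)
            assert np.array_equal(right.pixels, again.condition(cond_id)[1].pixels)

    def test_png_export_byte_identical(self, db, config, tmp_path):
        files_a = db.export_png(tmp_path / "a")
        files_b = build_database(config).export_png(tmp_path / "b")
        for fa, fb in zip(sorted(files_a), sorted(files_b)):
            assert fa.read_bytes() == fb.read_bytes()

    def test_layers_separate(self, db):
        left, _ = db.condition("squares/7")
        v, f = left.vernier_pixels > 0, left.flanker_pixels > 0
        assert not np.any(v & f)
        assert np.array_equal((left.pixels > 0), v | f)


class TestBoumaWindow:
    @pytest.mark.parametrize("ecc,expected", [(0, 0.0), (1, 0.5), (9, 4.5)])
    def test_half_eccentricity(self, ecc, expected):
        assert bouma_window(ecc) == pytest.approx(expected)

    def test_negative_eccentricity_rejected(self):
        with pytest.raises(ValueError):
            bouma_window(-1)
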