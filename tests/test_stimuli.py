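"""Stimulus rendering: sub-pixel shifts, the five stimulus classes, field mask."""

import numpy as np
import pytest

from chromasim import stimuli as st


@pytest.fixture(scope="module")
def canvas():
    return st.CanvasSpec(size_px=256)


@pytest.fixture(scope="module")
def small_canvas():
    return st.CanvasSpec(size_px=32)


@pytest.fixture(scope="module")
def noise_image(small_canvas):
    rng = np.random.default_rng(0)
    n = small_canvas.size_px
    return st.TriPrimaryImage(rng.random((n, n)), rng.random((n, n)), rng.random((n, n)))


def kron_shift_oracle(plane, subpixels, upsample, axis):
    """Literal up-sample / roll / box-average reference implementation."""
    up = np.repeat(plane, upsample, axis=axis)
    up = np.roll(up, subpixels, axis=axis)
    n = plane.shape[axis]
    if axis == 0:
        return up.reshape(n, upsample, -1).mean(axis=1)
    return up.reshape(plane.shape[0], n, upsample).mean(axis=2)


class TestSubpixelRender:
    def test_zero_offset_bit_identical(self, noise_image, small_canvas):
        out = st.render_subpixel(noise_image, {}, small_canvas)
        assert np.array_equal(out.blue, noise_image.blue)
        assert np.array_equal(out.green, noise_image.green)

    def test_matches_upsample_roll_downsample_oracle(self, noise_image, small_canvas):
        # 1.3 display pixels = 13 sub-pixels rightward
        out = st.render_subpixel(noise_image, {"blue": (0.23 * 1.3, 0.0)}, small_canvas)
        ref = kron_shift_oracle(noise_image.blue, 13, 10, axis=1)
        assert np.allclose(out.blue, ref, atol=1e-12)

    def test_integer_pixel_offset_equals_roll(self, noise_image, small_canvas):
        out = st.render_subpixel(noise_image, {"green": (0.23 * 7, 0.0)}, small_canvas)
        assert np.allclose(out.green, np.roll(noise_image.green, 7, axis=1))

    def test_commutes_with_whole_pixel_translation(self, noise_image, small_canvas):
        offs = {"blue": (0.23 * 0.4, 0.0)}
        shifted_then = st.render_subpixel(
            st.TriPrimaryImage(
                noise_image.red, noise_image.green, np.roll(noise_image.blue, 3, axis=1)
            ),
            offs,
            small_canvas,
        ).blue
        then_shifted = np.roll(
            st.render_subpixel(noise_image, offs, small_canvas).blue, 3, axis=1
        )
        assert np.allclose(shifted_then, then_shifted, atol=1e-12)

    def test_luminance_conserved_for_interior_content(self, small_canvas):
        n = small_canvas.size_px
        plane = np.zeros((n, n))
        plane[10:20, 10:20] = 0.7  # away from the wrap-around edges
        img = st.TriPrimaryImage(np.zeros_like(plane), np.zeros_like(plane), plane)
        out = st.render_subpixel(img, {"blue": (0.23 * 1.7, -0.23 * 0.6)}, small_canvas)
        assert out.blue.sum() == pytest.approx(plane.sum(), rel=1e-3)

    def test_subquantum_offset_warns(self, noise_image, small_canvas):
        with pytest.warns(st.SubpixelQuantizationWarning):
            st.render_subpixel(noise_image, {"blue": (0.01, 0.0)}, small_canvas)

    def test_red_plane_is_reference(self, noise_image, small_canvas):
        with pytest.raises(ValueError):
            st.render_subpixel(noise_image, {"red": (0.23, 0.0)}, small_canvas)


class TestTumblingE:
    def test_letter_is_20_percent_decrement(self, canvas):
        spec = st.TumblingESpec(logmar=0.8, background="green", background_luminance=0.9)
        img = st.make_tumbling_e(spec, canvas)
        vals = img.green[img.green > 0]
        assert vals.max() == pytest.approx(0.9, abs=1e-6)
        assert vals.min() == pytest.approx(0.9 * 0.8, abs=1e-6)

    def test_orientations_are_right_angle_rotations(self, canvas):
        base = {
            o: st.make_tumbling_e(
                st.TumblingESpec(orientation=o, logmar=0.8, background="green"), canvas
            ).green
            for o in ("R", "U", "L", "D")
        }
        rotations = {np.rot90(base["R"], k).tobytes() for k in range(4)}
        for o in ("U", "L", "D"):
            assert base[o].tobytes() in rotations

    def test_letter_size_scales_with_logmar(self, canvas):
        def height_px(logmar):
            img = st.make_tumbling_e(
                st.TumblingESpec(logmar=logmar, background="green"), canvas
            )
            letter = img.green < 0.9 * 0.85  # darker than background
            letter &= img.green > 0
            rows = np.nonzero(letter.any(axis=1))[0]
            return rows.max() - rows.min() + 1
        h1, h2 = height_px(0.5), height_px(0.5 + np.log10(2))
        assert h2 / h1 == pytest.approx(2.0, rel=0.05)

    def test_purple_background_equal_luminance_mix(self, canvas):
        img = st.make_tumbling_e(
            st.TumblingESpec(logmar=0.5, background="purple", background_luminance=0.9),
            canvas,
        )
        m = canvas.field_mask()
        assert img.red[m].max() == pytest.approx(img.green[m].max())
        assert img.green[m].max() == pytest.approx(img.blue[m].max())

    def test_oversized_letter_rejected(self, canvas):
        with pytest.raises(ValueError):
            st.make_tumbling_e(st.TumblingESpec(logmar=1.7), canvas)


class TestGaborComposite:
    def test_counterphase_sum_is_flat(self, canvas):
        img = st.make_gabor_composite(
            st.GaborCompositeSpec(blue_offset_arcmin=3.0, contrast=1.0), canvas
        )
        x, y = canvas.axes_arcmin()
        interior = np.hypot(*np.meshgrid(x, y)) < 20
        total = (img.red + img.blue)[interior]
        assert total.std() / total.mean() < 1e-10

    def test_in_phase_composite_is_single_luminance_grating(self, canvas):
        img = st.make_gabor_composite(
            st.GaborCompositeSpec(blue_offset_arcmin=0.0, contrast=0.8), canvas
        )
        mask = (img.red > 0) & (img.blue > 0)
        ratio = img.red[mask] / img.blue[mask]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-9)
        x, y = canvas.axes_arcmin()
        interior = np.hypot(*np.meshgrid(x, y)) < 15
        assert (img.red + img.blue)[interior].std() > 0.05

    def test_grating_period_on_canvas(self, canvas):
        # 10 cpd -> 6 arcmin -> 26.09 display pixels
        assert 60.0 / 10.0 / canvas.pixel_pitch_arcmin == pytest.approx(26.09, abs=0.01)
        img = st.make_gabor_composite(
            st.GaborCompositeSpec(blue_offset_arcmin=0.0, contrast=1.0, tilt_deg=10.0),
            canvas,
        )
        row = img.red[canvas.size_px // 2]
        spectrum = np.abs(np.fft.rfft(row - row.mean()))
        f_px = np.fft.rfftfreq(len(row))
        peak_period = 1.0 / f_px[np.argmax(spectrum)]
        # period along a horizontal cut is stretched by 1/cos(tilt)
        assert peak_period == pytest.approx(26.09 / np.cos(np.radians(10)), rel=0.05)

    def test_tilt_restricted(self):
        with pytest.raises(ValueError):
            st.GaborCompositeSpec(tilt_deg=5.0)


@pytest.fixture(scope="module")
def big_canvas():
    return st.CanvasSpec(size_px=512)


@pytest.fixture(scope="module")
def bar_canvas():
    return st.CanvasSpec(size_px=600)


class TestDuochrome:
    def test_concentric_at_zero_offset(self, big_canvas):
        img = st.make_duochrome(st.DuochromeSpec(), big_canvas)
        n = big_canvas.size_px
        idx = np.arange(n)
        cx_disk = (img.blue * idx).sum() / img.blue.sum()
        cx_ann = (img.red * idx).sum() / img.red.sum()
        assert cx_disk == pytest.approx(cx_ann, abs=0.01)

    def test_disk_diameter_half_degree(self, big_canvas):
        img = st.make_duochrome(st.DuochromeSpec(), big_canvas)
        cols = np.nonzero((img.blue > 0.5).any(axis=0))[0]
        diam_arcmin = (cols.max() - cols.min() + 1) * big_canvas.pixel_pitch_arcmin
        assert diam_arcmin == pytest.approx(29.9, abs=0.5)

    def test_five_pixel_offset_moves_centroid(self, big_canvas):
        ref = st.make_duochrome(st.DuochromeSpec(), big_canvas)
        off = st.make_duochrome(st.DuochromeSpec(disk_offset_px=(5.0, 0.0)), big_canvas)
        idx = np.arange(big_canvas.size_px)
        shift_px = (off.blue * idx).sum() / off.blue.sum() - (ref.blue * idx).sum() / ref.blue.sum()
        assert shift_px * big_canvas.pixel_pitch_arcmin == pytest.approx(1.15, abs=0.01)

    def test_green_disk_variant(self, big_canvas):
        img = st.make_duochrome(st.DuochromeSpec(disk_primary="green"), big_canvas)
        assert img.green.max() > 0.5
        assert img.blue.max() == 0.0

    def test_geometry_overflow_rejected(self, big_canvas):
        with pytest.raises(ValueError):
            st.make_duochrome(st.DuochromeSpec(disk_diameter_px=700), big_canvas)


class TestDichopticBars:
    def test_identical_at_zero_disparity(self, bar_canvas):
        L, R = st.make_dichoptic_bars(st.DichopticBarsSpec(), bar_canvas)
        assert np.array_equal(L.blue, R.blue)
        assert np.array_equal(L.red, R.red)

    def test_disparity_splits_between_eyes(self, bar_canvas):
        L, R = st.make_dichoptic_bars(
            st.DichopticBarsSpec(disparity_arcmin=1.15), bar_canvas
        )
        idx = np.arange(bar_canvas.size_px)
        dx_px = (L.blue * idx).sum() / L.blue.sum() - (R.blue * idx).sum() / R.blue.sum()
        assert dx_px == pytest.approx(5.0, abs=0.01)  # 1.15 arcmin = 5 px
        # red bars carry no disparity
        assert np.array_equal(L.red, R.red)

    def test_bar_dimensions_in_pixels(self, bar_canvas):
        L, _ = st.make_dichoptic_bars(st.DichopticBarsSpec(), bar_canvas)
        rows = np.nonzero(L.blue.any(axis=1))[0]
        assert rows.max() - rows.min() + 1 == pytest.approx(261, abs=1)
        # flux-based width is exact even when the bar straddles pixel borders
        peak_row = L.blue[L.blue.any(axis=1)][0]
        assert peak_row.sum() / peak_row.max() == pytest.approx(10.0, abs=0.1)


class TestVoronoi:
    def test_deterministic_for_fixed_seed(self, canvas):
        a = st.make_voronoi(st.VoronoiSpec(seed_count=20), 7, canvas)
        b = st.make_voronoi(st.VoronoiSpec(seed_count=20), 7, canvas)
        assert np.array_equal(a.green, b.green)

    def test_single_primary_only(self, canvas):
        img = st.make_voronoi(st.VoronoiSpec(seed_count=20, primary="red"), 3, canvas)
        assert img.red.max() > 0
        assert img.green.max() == 0.0 and img.blue.max() == 0.0

    def test_cell_count_matches_seed_count(self):
        # brute-force region labeling: count distinct luminance levels;
        # the field must fit the canvas so every cell is visible
        canvas = st.CanvasSpec(size_px=200, field_deg=0.6)
        spec = st.VoronoiSpec(seed_count=12, primary="green")
        img = st.make_voronoi(spec, 11, canvas)
        inside = canvas.field_mask() & (img.green > 0)
        assert len(np.unique(img.green[inside])) == 12

    def test_minimum_seed_count(self):
        with pytest.raises(ValueError):
            st.VoronoiSpec(seed_count=1)


class TestFieldMask:
    @pytest.mark.parametrize("maker, spec", [
        (st.make_tumbling_e, st.TumblingESpec(logmar=0.5)),
        (st.make_gabor_composite, st.GaborCompositeSpec(sigma_arcmin=10.0)),
        (st.make_voronoi, None),
    ])
    def test_stimuli_vanish_outside_field(self, maker, spec):
        # canvas wider than the circular field, so corners must stay dark
        wide = st.CanvasSpec(size_px=256, field_deg=0.8)
        if spec is None:
            img = st.make_voronoi(st.VoronoiSpec(seed_count=10), 0, wide)
        else:
            img = maker(spec, wide)
        outside = ~wide.field_mask()
        assert outside.any()
        for plane in img.planes.values():
            assert plane[outside].max() == 0.0
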