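"""Image encodings: rasterization contracts, RGB synthesis, round trips."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtransfer.encode import (DEFAULT_CHANNEL_MAP, EncodedImage, RasterSpec,
                                decode_rgb, encode_merged_chart, encode_rgb,
                                read_image, render_trace_bitmap, write_image,
                                write_image_dataset, read_image_dataset)
from eegtransfer.errors import InvalidArgumentError


class TestRenderTraceBitmap:
    def test_constant_half_trace_is_single_middle_row(self):
        spec = RasterSpec(width=41, height=41)
        plane = render_trace_bitmap(np.full(100, 0.5), spec)
        rows = np.nonzero((plane == 0).any(axis=1))[0]
        assert rows.tolist() == [20]
        assert (plane[20] == 0).all()

    def test_binary_contract(self, random_window):
        spec = RasterSpec(width=64, height=48)
        plane = render_trace_bitmap(random_window[0], spec)
        assert set(np.unique(plane)) <= {0, 255}

    def test_two_sample_ramp_on_two_columns(self):
        spec = RasterSpec(width=2, height=32)
        plane = render_trace_bitmap(np.array([0.0, 1.0]), spec)
        assert plane[31, 0] == 0      # value 0 -> bottom row, column 0
        assert plane[0, 1] == 0       # value 1 -> top row, column 1
        # the connecting polyline keeps each column's pixels contiguous
        for col in range(2):
            rows = np.nonzero(plane[:, col] == 0)[0]
            assert rows.size >= 1
            assert np.array_equal(rows, np.arange(rows[0], rows[-1] + 1))

    def test_nan_rejected(self):
        spec = RasterSpec(width=32, height=32)
        with pytest.raises(InvalidArgumentError):
            render_trace_bitmap(np.array([0.1, np.nan, 0.3]), spec)

    def test_too_short_trace_rejected(self):
        with pytest.raises(InvalidArgumentError):
            render_trace_bitmap(np.array([0.5]), RasterSpec())

    def test_determinism(self, random_window):
        spec = RasterSpec(width=48, height=48)
        a = render_trace_bitmap(random_window[0], spec)
        b = render_trace_bitmap(random_window[0], spec)
        assert np.array_equal(a, b)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_binary_purity_property(self, values):
        spec = RasterSpec(width=40, height=36)
        plane = render_trace_bitmap(np.array(values), spec)
        assert set(np.unique(plane)) <= {0, 255}
        assert (plane == 0).any()  # a polyline always marks pixels


class TestRasterSpec:
    def test_equal_line_and_background_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RasterSpec(line_value=255, background_value=255)

    def test_antialias_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RasterSpec(antialias=True)

    def test_small_canvas_rejected_for_encoding(self, random_window):
        spec = RasterSpec(width=16, height=16)
        with pytest.raises(InvalidArgumentError):
            encode_merged_chart(random_window, spec)


class TestMergedChart:
    def test_overdraw_idempotent_for_identical_traces(self, small_raster):
        trace = np.linspace(0.1, 0.9, 250)
        window = np.stack([trace, trace, trace])
        merged = encode_merged_chart(window, small_raster)
        single = render_trace_bitmap(trace, small_raster)
        assert np.array_equal(merged.pixels, single)

    def test_grayscale_binary_contract(self, random_window, small_raster):
        img = encode_merged_chart(random_window, small_raster)
        assert img.pixels.ndim == 2
        assert set(np.unique(img.pixels)) <= {0, 255}
        assert img.encoding == "merged_chart"

    def test_three_constant_traces_give_three_rows(self):
        spec = RasterSpec(width=41, height=41)
        window = np.stack([np.full(100, v) for v in (0.25, 0.5, 0.75)])
        img = encode_merged_chart(window, spec)
        rows = np.nonzero((img.pixels == 0).any(axis=1))[0]
        # y = round((1-v)*(h-1)): 0.75->10, 0.5->20, 0.25->30
        assert rows.tolist() == [10, 20, 30]

    def test_axes_drawn_when_requested(self, random_window):
        spec = RasterSpec(width=48, height=48, draw_axes=True)
        img = encode_merged_chart(random_window, spec)
        assert (img.pixels[-1, :] == 0).all()
        assert (img.pixels[:, 0] == 0).all()


class TestRGBSynthesis:
    def test_single_channel_trace_pixel_colors(self, small_raster):
        # Fp1 oscillates; Fpz/Fp2 flat at distinct rows
        window = np.stack([np.linspace(0, 1, 250),
                           np.full(250, 0.2), np.full(250, 0.8)])
        img = encode_rgb(window, small_raster)
        only_r = (img.pixels[:, :, 0] == 0) & (img.pixels[:, :, 1] == 255) \
            & (img.pixels[:, :, 2] == 255)
        assert only_r.any()
        # background pixels are white
        bg = (img.pixels == 255).all(axis=2)
        assert bg.any()

    def test_identical_traces_give_black_silhouette(self, small_raster):
        trace = np.linspace(0.1, 0.9, 250)
        window = np.stack([trace] * 3)
        img = encode_rgb(window, small_raster)
        mask = render_trace_bitmap(trace, small_raster) == 0
        assert (img.pixels[mask] == 0).all()
        assert (img.pixels[~mask] == 255).all()

    def test_axes_forbidden(self, random_window):
        spec = RasterSpec(width=48, height=48, draw_axes=True)
        with pytest.raises(InvalidArgumentError):
            encode_rgb(random_window, spec)

    def test_decode_is_inverse_of_encode(self, random_window, small_raster):
        img = encode_rgb(random_window, small_raster)
        masks = decode_rgb(img)
        for mask, trace in zip(masks, random_window):
            expected = render_trace_bitmap(trace, small_raster) == 0
            assert np.array_equal(mask, expected)

    def test_decode_rejects_gray(self):
        px = np.full((32, 32, 3), 128, dtype=np.uint8)
        img = EncodedImage(px, "rgb_synthesis")
        with pytest.raises(InvalidArgumentError):
            decode_rgb(img)

    def test_decode_all_white_gives_empty_masks(self):
        px = np.full((32, 32, 3), 255, dtype=np.uint8)
        masks = decode_rgb(EncodedImage(px, "rgb_synthesis"))
        assert all(not m.any() for m in masks)

    def test_channel_permutation_equivariance(self, random_window, small_raster):
        base = encode_rgb(random_window, small_raster, DEFAULT_CHANNEL_MAP)
        base_planes = {name: base.pixels[:, :, i]
                       for i, name in enumerate(DEFAULT_CHANNEL_MAP)}
        for perm in itertools.permutations(DEFAULT_CHANNEL_MAP):
            img = encode_rgb(random_window, small_raster, perm)
            for i, name in enumerate(perm):
                assert np.array_equal(img.pixels[:, :, i], base_planes[name])

    def test_invalid_channel_map_rejected(self, random_window, small_raster):
        with pytest.raises(InvalidArgumentError):
            encode_rgb(random_window, small_raster, ("Fp1", "Fp1", "Fp2"))


class TestImageIO:
    def test_png_roundtrip_rgb(self, tmp_path, random_window, small_raster):
        img = encode_rgb(random_window, small_raster, subject_id="S1",
                         label="healthy", window_index=3)
        path = tmp_path / "img.png"
        write_image(img, path)
        back = read_image(path, "rgb_synthesis", "S1", "healthy", 3)
        assert np.array_equal(back.pixels, img.pixels)

    def test_dataset_manifest_roundtrip(self, tmp_path, random_window, small_raster):
        imgs = [encode_merged_chart(random_window, small_raster,
                                    subject_id=f"S{i}", label="depressed",
                                    window_index=i) for i in range(3)]
        manifest = write_image_dataset(imgs, tmp_path / "imgs")
        back = read_image_dataset(manifest)
        assert len(back) == 3
        for a, b in zip(imgs, back):
            assert np.array_equal(a.pixels, b.pixels)
            assert b.label == "depressed"
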