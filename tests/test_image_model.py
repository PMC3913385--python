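"""Image I/O, deinterlacing and ROI rasterization."""

import numpy as np
import pytest
from PIL import Image

from plaquantify import (
    EllipseROI,
    FluorescenceImage,
    PolygonROI,
    deinterlace,
    rasterize_ellipse,
    rasterize_polygon,
    read_image,
    write_image,
)
from plaquantify.errors import FormatError, GeometryError
from plaquantify.image_model import load_rois, save_rois

from conftest import point_in_polygon, star_polygon


class TestReadWrite:
    def test_all_black_png(self, tmp_path):
        p = tmp_path / "black.png"
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(p)
        img = read_image(p)
        assert img.pixels.shape == (4, 4, 3)
        assert (img.pixels == 0).all()

    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_round_trip_preserves_pixels(self, tmp_path, rng, suffix):
        arr = rng.integers(0, 256, (7, 5, 3), dtype=np.uint8)
        p = tmp_path / f"rt{suffix}"
        write_image(FluorescenceImage(arr), p)
        assert (read_image(p).pixels == arr).all()

    def test_16bit_tiff_rejected(self, tmp_path):
        p = tmp_path / "deep.tif"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint16)).save(p)
        with pytest.raises(FormatError, match="RGB"):
            read_image(p)

    def test_grayscale_rejected(self, tmp_path):
        p = tmp_path / "gray.png"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(p)
        with pytest.raises(FormatError, match="mode 'L'"):
            read_image(p)

    def test_mm_per_pixel_must_be_positive(self):
        with pytest.raises(FormatError):
            FluorescenceImage(np.zeros((4, 4, 3), dtype=np.uint8), mm_per_pixel=0.0)


class TestDeinterlace:
    def test_constant_image_is_fixed_point(self):
        img = FluorescenceImage(np.full((6, 4, 3), 77, dtype=np.uint8))
        assert (deinterlace(img).pixels == 77).all()

    def test_three_row_column(self):
        col = np.zeros((3, 2, 3), dtype=np.uint8)
        col[1] = 100
        out = deinterlace(FluorescenceImage(col), field="odd_rows")
        assert (out.pixels == 0).all()

    def test_even_field_boundary_rows_copy_neighbour(self):
        arr = np.zeros((4, 2, 3), dtype=np.uint8)
        arr[1] = 40
        arr[3] = 200
        out = deinterlace(FluorescenceImage(arr), field="even_rows").pixels
        assert (out[0] == 40).all()  # row 0 takes its only neighbour
        assert (out[2] == 120).all()  # mean of rows 1 and 3
        assert (out[1] == 40).all() and (out[3] == 200).all()  # untouched

    @pytest.mark.parametrize("field", ["odd_rows", "even_rows"])
    def test_matches_row_by_row_oracle(self, rng, field):
        arr = rng.integers(0, 256, (11, 6, 3), dtype=np.uint8)
        out = deinterlace(FluorescenceImage(arr), field=field).pixels
        parity = 1 if field == "odd_rows" else 0
        expect = arr.astype(int).copy()
        h = arr.shape[0]
        for i in range(parity, h, 2):
            if i == 0:
                expect[i] = arr[1]
            elif i == h - 1:
                expect[i] = arr[h - 2]
            else:
                for j in range(arr.shape[1]):
                    for c in range(3):
                        expect[i, j, c] = (int(arr[i - 1, j, c]) + int(arr[i + 1, j, c]) + 1) // 2
        assert (out == expect).all()

    def test_too_few_rows(self):
        with pytest.raises(FormatError):
            deinterlace(FluorescenceImage(np.zeros((2, 4, 3), dtype=np.uint8)))


class TestRasterizePolygon:
    def test_integer_rectangle_area_exact(self):
        roi = PolygonROI([(0, 0), (4, 0), (4, 3), (0, 3)])
        assert rasterize_polygon(roi, 10, 10).count == 12

    def test_degenerate_collinear_polygon_is_empty(self):
        roi = PolygonROI([(1, 1), (3, 3), (5, 5)])
        assert rasterize_polygon(roi, 8, 8).count == 0

    def test_self_intersecting_rejected(self):
        bowtie = PolygonROI([(0, 0), (4, 4), (4, 0), (0, 4)])
        with pytest.raises(GeometryError):
            rasterize_polygon(bowtie, 8, 8)

    def test_triangle_matches_point_in_polygon_oracle(self):
        roi = PolygonROI([(0.7, 0.2), (6.3, 1.9), (2.1, 6.8)])
        mask = rasterize_polygon(roi, 8, 8).pixels
        for i in range(8):
            for j in range(8):
                assert mask[i, j] == point_in_polygon(j + 0.5, i + 0.5, roi.vertices)

    def test_random_simple_polygons_match_oracle(self, rng):
        for _ in range(25):
            h, w = int(rng.integers(8, 33)), int(rng.integers(8, 33))
            roi = star_polygon(rng, h, w)
            mask = rasterize_polygon(roi, h, w).pixels
            oracle = np.zeros((h, w), dtype=bool)
            for i in range(h):
                for j in range(w):
                    oracle[i, j] = point_in_polygon(j + 0.5, i + 0.5, roi.vertices)
            assert (mask == oracle).all()

    def test_dilation_grows_mask(self):
        inner = PolygonROI([(3, 3), (9, 3), (9, 9), (3, 9)])
        outer = PolygonROI([(2, 2), (10, 2), (10, 10), (2, 10)])
        m_in = rasterize_polygon(inner, 14, 14).pixels
        m_out = rasterize_polygon(outer, 14, 14).pixels
        assert (m_in <= m_out).all() and m_out.sum() > m_in.sum()


class TestRasterizeEllipse:
    def test_small_circle_at_pixel_centre(self):
        roi = EllipseROI(center=(3.5, 4.5), semi_axes=(0.6, 0.6))
        mask = rasterize_ellipse(roi, 10, 10)
        assert mask.count == 1
        assert mask.pixels[4, 3]

    def test_matches_inequality_oracle(self, rng):
        roi = EllipseROI(center=(8.3, 6.1), semi_axes=(4.2, 2.7), rotation=0.0)
        mask = rasterize_ellipse(roi, 16, 20).pixels
        for i in range(16):
            for j in range(20):
                dx, dy = (j + 0.5) - 8.3, (i + 0.5) - 6.1
                assert mask[i, j] == ((dx / 4.2) ** 2 + (dy / 2.7) ** 2 <= 1.0)

    def test_rotation_90_swaps_axes(self):
        rot = rasterize_ellipse(
            EllipseROI(center=(10, 10), semi_axes=(5, 2), rotation=90.0), 20, 20
        )
        swapped = rasterize_ellipse(
            EllipseROI(center=(10, 10), semi_axes=(2, 5), rotation=0.0), 20, 20
        )
        assert (rot.pixels == swapped.pixels).all()

    def test_nonpositive_semi_axis_rejected(self):
        with pytest.raises(GeometryError):
            EllipseROI(center=(5, 5), semi_axes=(0.0, 2.0))

    def test_centre_outside_image_rejected(self):
        roi = EllipseROI(center=(30, 5), semi_axes=(2, 2))
        with pytest.raises(GeometryError):
            rasterize_ellipse(roi, 10, 10)


class TestRoiJson:
    def test_round_trip(self, tmp_path):
        records = [
            {
                "image_id": "im1",
                "tooth_id": "13",
                "type": "polygon",
                "roi": PolygonROI([(1.5, 2.0), (8.0, 2.5), (4.0, 9.0)], tooth_id="13"),
            },
            {
                "image_id": "im1",
                "tooth_id": "13",
                "type": "ellipse",
                "roi": EllipseROI(center=(4.0, 4.0), semi_axes=(2.0, 1.0), rotation=30.0),
            },
        ]
        p = tmp_path / "rois.json"
        save_rois(records, p)
        loaded = load_rois(p)
        assert loaded[0]["roi"].vertices == records[0]["roi"].vertices
        assert loaded[1]["roi"].center == (4.0, 4.0)
        assert loaded[1]["roi"].rotation == 30.0

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(GeometryError):
            PolygonROI([(0, 0), (1, 1)])
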