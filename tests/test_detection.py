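import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cellpick import (
    IMAGEJ_DIALECT,
    ArenaGeometry,
    DetectionParams,
    ExternalDetectionDialect,
    FrameSpec,
    RenderParams,
    detect_mosaic,
    import_external_detections,
    local_variance_map,
    segment_frame,
)
from cellpick.synthetic import MosaicScan, MosaicTile, generate_mosaic, render_frame

from conftest import cell


def brute_force_variance(img, r):
    """Reference implementation: explicit window variance with edge reflection
    (numpy's "symmetric" padding: the border pixel is repeated)."""
    padded = np.pad(img.astype(float), r, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = win.var()
    return out


class TestLocalVarianceMap:
    def test_constant_image_gives_zero(self):
        assert (local_variance_map(np.full((20, 20), 7.0), 2) == 0).all()

    def test_matches_brute_force_on_random_image(self, rng):
        img = rng.uniform(0, 1000, size=(7, 7))
        got = local_variance_map(img, 1)
        want = brute_force_variance(img, 1)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(
        img=hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=5, max_side=12),
            elements=st.floats(0, 1000),
        ),
        r=st.integers(1, 2),
    )
    def test_brute_force_property(self, img, r):
        np.testing.assert_allclose(
            local_variance_map(img, r), brute_force_variance(img, r), rtol=1e-9, atol=1e-6
        )

    def test_step_edge_peaks_at_edge(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 100.0
        var = local_variance_map(img, 1)
        assert var[:, 9:11].min() > 0
        # windows at the edge see 3 or 6 of 9 pixels high: var = 10000*2/9
        assert var[10, 9] == pytest.approx(10000 * 2 / 9, rel=1e-9)
        assert (var[:, :8] == 0).all() and (var[:, 12:] == 0).all()


class TestSegmentFrame:
    def test_blank_noisy_frame_detects_nothing(self, rng):
        spec = FrameSpec(256, 256, 2.0)
        img = render_frame([], spec, RenderParams(noise_sd=5.0, seed=1))
        assert segment_frame(img, spec, DetectionParams()) == []

    def test_separated_spots_all_found_within_one_pixel(self, noiseless):
        spec = FrameSpec(400, 400, 2.0)
        truth = [cell(x=100.0 + 150 * (i % 5), y=100.0 + 300 * (i // 5), cid=i) for i in range(10)]
        img = render_frame(truth, spec, noiseless)
        recs = segment_frame(img, spec, DetectionParams())
        assert len(recs) == 10
        for t in truth:
            d = min(np.hypot(r.x - t.x, r.y - t.y) for r in recs)
            assert d <= spec.pixel_size

    def test_brightness_ceiling_filters_one_spot(self, noiseless):
        spec = FrameSpec(400, 400, 2.0)
        truth = [cell(x=100.0 + 150 * (i % 5), y=100.0 + 300 * (i // 5), cid=i) for i in range(10)]
        img = render_frame(truth, spec, noiseless).astype(float)
        base = segment_frame(img, spec, DetectionParams())
        # normal spots image at ~equal mean brightness; the boosted one is ~10x
        ceiling = max(r.brightness for r in base) * 2.0
        bright = truth[:]
        bright[3] = cell(x=truth[3].x, y=truth[3].y, cid=3, brightness=5000.0)
        img2 = render_frame(bright, spec, noiseless)
        recs = segment_frame(img2, spec, DetectionParams(max_brightness=ceiling))
        assert len(recs) == 9

    def test_counts_monotone_in_filters(self, rng):
        spec = FrameSpec(300, 300, 2.0)
        truth = [cell(x=float(x), y=float(y), cid=i)
                 for i, (x, y) in enumerate(rng.uniform(50, 550, size=(12, 2)))]
        img = render_frame(truth, spec, RenderParams(noise_sd=4.0, seed=5))
        counts_b = [
            len(segment_frame(img, spec, DetectionParams(min_brightness=b)))
            for b in (0, 100, 150, 200, 400)
        ]
        assert counts_b == sorted(counts_b, reverse=True)
        counts_s = [
            len(segment_frame(img, spec, DetectionParams(min_size=s)))
            for s in (2, 10, 20, 30, 50)
        ]
        assert counts_s == sorted(counts_s, reverse=True)

    def test_invariant_to_constant_offset(self, noiseless):
        spec = FrameSpec(200, 200, 2.0)
        img = render_frame([cell(200, 200)], spec, noiseless).astype(np.float64)
        base = segment_frame(img, spec, DetectionParams())
        shifted = segment_frame(
            img + 300.0, spec, DetectionParams(min_brightness=0, max_brightness=1e9)
        )
        assert len(base) == len(shifted) == 1
        assert shifted[0].x == pytest.approx(base[0].x, abs=1e-6)
        assert shifted[0].size == pytest.approx(base[0].size)
        assert shifted[0].brightness == pytest.approx(base[0].brightness + 300.0)


class TestDetectMosaic:
    def _mosaic(self, cells, arena_side=700.0, overlap=0.25):
        arena = ArenaGeometry.square(arena_side)
        spec = FrameSpec(200, 200, 2.0)
        return generate_mosaic(arena, cells, spec, overlap, RenderParams(noise_sd=0.0))

    def test_overlap_duplicate_merged_to_single_record(self):
        mosaic = self._mosaic([cell(x=350.0, y=100.0)])
        recs = detect_mosaic(mosaic, DetectionParams(), dedup_radius=20.0)
        assert len(recs) == 1
        assert recs[0].x == pytest.approx(350.0, abs=2.0)

    def test_single_tile_equals_segment_frame(self, noiseless):
        arena = ArenaGeometry.square(300.0)
        spec = FrameSpec(200, 200, 2.0)
        mosaic = generate_mosaic(arena, [cell(150, 150)], spec, 0.0, noiseless)
        assert mosaic.n_tiles == 1
        tile = mosaic.tiles[0]
        direct = segment_frame(tile.image, tile.spec, DetectionParams())
        merged = detect_mosaic(mosaic, DetectionParams(), 20.0)
        assert [(r.x, r.y) for r in merged] == [(r.x, r.y) for r in direct]

    def test_cells_outside_overlaps_all_recovered(self):
        cells = [cell(x=100.0 + 160 * i, y=120.0, cid=i) for i in range(4)]
        mosaic = self._mosaic(cells, arena_side=700.0, overlap=0.0)
        recs = detect_mosaic(mosaic, DetectionParams(), 20.0)
        assert len(recs) == 4
        for t in cells:
            assert min(np.hypot(r.x - t.x, r.y - t.y) for r in recs) <= 2.0
        assert len({r.id for r in recs}) == 4

    def test_inconsistent_pixel_sizes_rejected(self, noiseless):
        s1 = FrameSpec(100, 100, 2.0)
        s2 = FrameSpec(100, 100, 1.0, stage_offset=(200.0, 0.0))
        tiles = (
            MosaicTile(render_frame([], s1, noiseless), s1, (0, 0)),
            MosaicTile(render_frame([], s2, noiseless), s2, (0, 1)),
        )
        with pytest.raises(ValueError, match="pixel size"):
            detect_mosaic(MosaicScan(tiles, 0.0, 2.0), DetectionParams())


class TestImportExternalDetections:
    IMAGEJ = " ,Area,Mean,XStart,YStart\n1,55,210.5,10,20\n2,42,180.0,100,250\n3,60,330.25,400,5\n"

    def test_imagej_rows_hand_converted(self):
        spec = FrameSpec(640, 640, 1.3, stage_offset=(100.0, 200.0))
        recs = import_external_detections(io.StringIO(self.IMAGEJ), IMAGEJ_DIALECT, spec)
        assert len(recs) == 3
        assert recs[0].x == pytest.approx(10 * 1.3 + 100)
        assert recs[0].y == pytest.approx(20 * 1.3 + 200)
        assert recs[0].brightness == pytest.approx(210.5)
        assert recs[2].x == pytest.approx(400 * 1.3 + 100)

    def test_micrometer_units_pass_through(self):
        dialect = ExternalDetectionDialect(x=("x_um",), y=("y_um",), units="um")
        recs = import_external_detections(
            io.StringIO("x_um,y_um\n12.5,7.25\n"), dialect, FrameSpec(10, 10, 1.3)
        )
        assert (recs[0].x, recs[0].y) == (12.5, 7.25)

    def test_header_only_file_yields_empty_list(self):
        recs = import_external_detections(
            io.StringIO("X,Y,Mean\n"), IMAGEJ_DIALECT, FrameSpec(10, 10, 1.0)
        )
        assert recs == []

    def test_missing_y_column_is_an_error(self):
        with pytest.raises(ValueError, match="y column"):
            import_external_detections(
                io.StringIO("XStart,Mean\n1,2\n"), IMAGEJ_DIALECT, FrameSpec(10, 10, 1.0)
            )

    def test_non_numeric_cell_reports_row(self):
        bad = "XStart,YStart\n1,2\n3,oops\n"
        with pytest.raises(ValueError, match="row 2"):
            import_external_detections(
                io.StringIO(bad), IMAGEJ_DIALECT, FrameSpec(10, 10, 1.0)
            )
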