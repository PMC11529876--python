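import numpy as np
import pytest
from shapely.geometry import LineString, Point

from emma import compositor, fixtures
from emma.compositor import (
    AlphaMaskSet,
    Seam,
    SeamSpec,
    composite,
    feather_masks,
    grid_seams,
    hard_composite,
    seam_path,
    seam_step_metric,
    signed_seam_distance,
)
from emma.errors import ConfigurationError
from emma.stitcher import MosaicLayout, Tile

from conftest import make_test_montage


def _two_tile_layout(tile=128, step=90, delta=0):
    """Horizontally adjacent constant tiles differing by delta grey levels."""
    a = Tile(np.full((tile, tile), 100, dtype=np.uint8), 0, 0)
    b = Tile(np.full((tile, tile), 100 + delta, dtype=np.uint8), 0, 1)
    layout = MosaicLayout({(0, 0): (0.0, 0.0), (0, 1): (float(step), 0.0)},
                          step + tile, tile)
    return [a, b], layout


class TestSeamPath:
    BAND = (90.0, 0.0, 128.0, 200.0)

    def test_roughness_zero_is_straight_midline(self):
        pts = seam_path(self.BAND, "vertical", SeamSpec(roughness_px=0, seed=1))
        assert np.allclose(pts[:, 0], 109.0)
        assert pts[0, 1] == 0.0 and pts[-1, 1] == 200.0

    def test_same_seed_identical(self):
        spec = SeamSpec(roughness_px=8, seed=7)
        assert np.array_equal(seam_path(self.BAND, "vertical", spec),
                              seam_path(self.BAND, "vertical", spec))

    def test_monotonic_along_axis(self):
        pts = seam_path(self.BAND, "vertical", SeamSpec(roughness_px=10, seed=3))
        assert np.all(np.diff(pts[:, 1]) > 0)

    def test_bounded_walk_statistics(self):
        # 1000 seams: excursion never exceeds roughness, mean stays near 0
        excursions = []
        means = []
        for seed in range(1000):
            pts = seam_path(self.BAND, "vertical", SeamSpec(roughness_px=10, seed=seed))
            lat = pts[:, 0] - 109.0
            excursions.append(np.abs(lat).max())
            means.append(lat.mean())
        assert max(excursions) <= 10.0
        assert abs(np.mean(means)) < 1.0

    def test_narrow_band_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="narrow"):
            pts = seam_path((100.0, 0.0, 112.0, 50.0), "vertical",
                            SeamSpec(roughness_px=10, seed=2))
        assert np.allclose(pts[:, 0], 106.0)

    def test_horizontal_axis(self):
        pts = seam_path((0.0, 90.0, 200.0, 128.0), "horizontal",
                        SeamSpec(roughness_px=5, seed=4))
        assert pts[0, 0] == 0.0 and pts[-1, 0] == 200.0
        assert np.abs(pts[:, 1] - 109.0).max() <= 5.0


class TestFeatherMasks:
    def _setup(self, feather, roughness=6, seed=0):
        tiles, layout = _two_tile_layout()
        spec = SeamSpec(roughness_px=roughness, feather_px=feather, seed=seed)
        seams = grid_seams(layout, (128, 128), 1, 2, spec)
        masks = feather_masks(layout, seams, feather, (128, 128))
        return tiles, layout, seams, masks

    def test_feather_zero_gives_binary_masks(self):
        _, _, _, masks = self._setup(feather=0)
        for m in masks.masks.values():
            assert set(np.unique(m)) <= {0.0, 0.5, 1.0}  # 0.5 only exactly on the seam

    def test_partition_of_unity_at_random_covered_pixels(self, rng):
        _, _, _, masks = self._setup(feather=15)
        total = masks.coverage()
        ys = rng.integers(0, total.shape[0], 10_000)
        xs = rng.integers(0, total.shape[1], 10_000)
        vals = total[ys, xs]
        covered = vals[vals > 0]
        assert np.allclose(covered, 1.0, atol=1e-6)

    def test_ramp_matches_exact_polyline_distance_oracle(self, rng):
        feather = 10  # small enough that no per-seam clamping kicks in
        _, layout, seams, masks = self._setup(feather=feather)
        seam = seams[0]
        line = LineString(seam.points)
        mask_a = masks.masks[(0, 0)]
        # sample strictly inside both footprints so renormalization is a
        # two-tile affair and the ramp formula applies directly
        for _ in range(200):
            x = int(rng.integers(92, 126))
            y = int(rng.integers(2, 126))
            d = line.distance(Point(x, y))
            side = 1.0 if x <= np.interp(y, seam.points[:, 1], seam.points[:, 0]) else -1.0
            expected = np.clip(0.5 + side * d / (2 * feather), 0.0, 1.0)
            assert np.isclose(mask_a[y, x], expected, atol=1e-6)

    def test_oversized_feather_clamped_to_band(self):
        # feather wider than the overlap band must not leave a truncated
        # ramp (a mask step) at the tile footprint edge
        tiles, layout = _two_tile_layout(delta=20)
        spec = SeamSpec(roughness_px=6, feather_px=60, seed=1)
        seams = grid_seams(layout, (128, 128), 1, 2, spec)
        masks = feather_masks(layout, seams, 60, (128, 128))
        out = composite(tiles, layout, masks).astype(float)
        # no step anywhere near the size of the injected mismatch
        assert np.abs(np.diff(out, axis=1)).max() <= 2.0

    def test_signed_distance_antisymmetry(self):
        _, _, seams, _ = self._setup(feather=10)
        seam = seams[0]
        xs = np.array([95.0, 100.0, 115.0])
        ys = np.array([10.0, 50.0, 100.0])
        da = signed_seam_distance(seam, xs, ys, "a")
        db = signed_seam_distance(seam, xs, ys, "b")
        assert np.allclose(da, -db)


class TestComposite:
    def test_single_tile_bit_exact(self):
        tile = Tile(np.arange(64 * 64, dtype=np.uint16).reshape(64, 64) % 500, 0, 0)
        layout = MosaicLayout({(0, 0): (0.0, 0.0)}, 64, 64)
        masks = feather_masks(layout, [], 10, (64, 64))
        out = composite([tile], layout, masks)
        assert np.array_equal(out, tile.pixels)

    def test_identical_content_overlap_equals_input(self, clean_montage_2x2):
        phantom, tiles, truth = clean_montage_2x2
        spec = SeamSpec(roughness_px=8, feather_px=12, seed=5)
        seams = grid_seams(truth.layout, tiles[0].pixels.shape, 2, 2, spec)
        masks = feather_masks(truth.layout, seams, 12, tiles[0].pixels.shape)
        out = composite(tiles, truth.layout, masks)
        assert np.array_equal(out, phantom)

    def test_feathered_seam_gradient_bounded(self):
        delta, feather = 20, 40
        tiles, layout = _two_tile_layout(delta=delta)
        spec = SeamSpec(roughness_px=6, feather_px=feather, seed=3)
        seams = grid_seams(layout, (128, 128), 1, 2, spec)
        masks = feather_masks(layout, seams, feather, (128, 128))
        out = composite(tiles, layout, masks).astype(float)
        grad = np.abs(np.diff(out, axis=1)).max()
        assert grad <= delta / (2 * feather) + 1.0

    def test_coverage_hole_warns_and_fills_background(self):
        a = Tile(np.full((64, 64), 50, dtype=np.uint8), 0, 0)
        layout = MosaicLayout({(0, 0): (0.0, 0.0)}, 64, 64)
        # weight map with a dead interior region: surrounded by coverage on
        # all sides, so it counts as a hole (unlike ragged jitter edges)
        m = np.ones((64, 64))
        m[30:34, 30:34] = 0.0
        masks = AlphaMaskSet({(0, 0): m}, (64, 64))
        with pytest.warns(UserWarning, match="16 uncovered"):
            out = composite([a], layout, masks)
        assert out[32, 32] == 0
        assert out[0, 0] == 50

    def test_ragged_jitter_edges_do_not_warn(self):
        import warnings as _warnings

        _, tiles, truth = make_test_montage(seed=6, jitter=4)
        masks = feather_masks(truth.layout, [], 0, tiles[0].pixels.shape)
        with _warnings.catch_warnings():
            _warnings.simplefilter("error")
            composite(tiles, truth.layout, masks)

    def test_deterministic_given_seed(self, clean_montage_2x2):
        _, tiles, truth = clean_montage_2x2
        spec = SeamSpec(roughness_px=8, feather_px=12, seed=9)
        outs = []
        for _ in range(2):
            seams = grid_seams(truth.layout, tiles[0].pixels.shape, 2, 2, spec)
            masks = feather_masks(truth.layout, seams, 12, tiles[0].pixels.shape)
            outs.append(composite(tiles, truth.layout, masks))
        assert np.array_equal(outs[0], outs[1])


class TestHardComposite:
    def test_identical_content_matches_feathered(self, clean_montage_2x2):
        phantom, tiles, truth = clean_montage_2x2
        assert np.array_equal(hard_composite(tiles, truth.layout), phantom)

    def test_step_of_exactly_delta_at_border(self):
        tiles, layout = _two_tile_layout(delta=20)
        out = hard_composite(tiles, layout).astype(float)
        assert np.abs(np.diff(out, axis=1)).max() == 20.0


class TestSeamStepMetric:
    def test_constant_mosaic_zero(self):
        seam = Seam("vertical", (0, 0), (0, 1),
                    np.array([[50.0, 0.0], [50.0, 99.0]]), (40.0, 0.0, 60.0, 99.0))
        mosaic = np.full((100, 100), 80, dtype=np.uint8)
        assert seam_step_metric(mosaic, [seam]) == 0.0

    def test_hard_step_measured_exactly(self):
        seam = Seam("vertical", (0, 0), (0, 1),
                    np.array([[50.0, 0.0], [50.0, 99.0]]), (40.0, 0.0, 60.0, 99.0))
        mosaic = np.full((100, 100), 80, dtype=np.uint8)
        mosaic[:, 50:] += 20
        assert seam_step_metric(mosaic, [seam]) == 20.0

    def test_feathered_below_hard_on_brightness_mismatch(self):
        # the irregular+fading projection beats straight borders on every
        # seed; smooth-texture phantom so content edges do not mask the step
        for seed in range(5):
            sspec = fixtures.SliceSpec(rows=2, cols=2, tile_width=128,
                                       tile_height=128, brightness_jitter=0.1,
                                       seed=seed)
            pspec = fixtures.PhantomSpec(seed=seed + 1000, n_blobs=0,
                                         membrane_density=0.0)
            _, tiles, truth = fixtures.make_montage(pspec, sspec)
            spec = SeamSpec(roughness_px=8, feather_px=15, seed=seed)
            shape = tiles[0].pixels.shape
            seams = grid_seams(truth.layout, shape, 2, 2, spec)
            masks = feather_masks(truth.layout, seams, 15, shape)
            soft = composite(tiles, truth.layout, masks)
            hard = hard_composite(tiles, truth.layout)
            half = (128 - truth.step_x) // 2 + 4
            m_soft = seam_step_metric(soft, seams, half_width=half)
            m_hard = seam_step_metric(hard, seams, half_width=half)
            assert m_soft < m_hard


class TestSeamSpecValidation:
    def test_negative_roughness_rejected(self):
        with pytest.raises(ConfigurationError):
            SeamSpec(roughness_px=-1)

    def test_zero_step_rejected(self):
        with pytest.raises(ConfigurationError):
            SeamSpec(step_px=0)


class TestGridSeams:
    def test_one_seam_per_adjacency(self, clean_montage_2x2):
        _, tiles, truth = clean_montage_2x2
        seams = grid_seams(truth.layout, tiles[0].pixels.shape, 2, 2, SeamSpec(seed=1))
        assert len(seams) == 4
        assert sum(s.axis == "vertical" for s in seams) == 2
        assert sum(s.axis == "horizontal" for s in seams) == 2

    def test_deterministic_per_pair_seeding(self, clean_montage_2x2):
        _, tiles, truth = clean_montage_2x2
        shape = tiles[0].pixels.shape
        a = grid_seams(truth.layout, shape, 2, 2, SeamSpec(roughness_px=6, seed=2))
        b = grid_seams(truth.layout, shape, 2, 2, SeamSpec(roughness_px=6, seed=2))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.points, sb.points)

    def test_export_seams_is_json_ready(self, clean_montage_2x2):
        import json

        _, tiles, truth = clean_montage_2x2
        seams = grid_seams(truth.layout, tiles[0].pixels.shape, 2, 2, SeamSpec(seed=1))
        text = json.dumps(compositor.export_seams(seams))
        assert json.loads(text)["seams"][0]["axis"] in ("vertical", "horizontal")
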