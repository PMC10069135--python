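"""Tests of clipping, denoising, ground filtering, normalization, extraction."""

import numpy as np
import pandas as pd
import pytest

from canoheight.errors import CanoheightError, ConfigError, FormatError
from canoheight.pointcloud_prep import (
    apply_min_height_filter,
    clip_to_extent,
    denoise,
    extract_plots,
    filter_ground,
    normalize,
    read_pointcloud,
    read_xyz,
    write_xyz,
)
from canoheight.synthetic_field import SensorModel, sample_pointcloud, synthesize_surface


class TestIO:
    def test_three_line_file(self, tmp_path):
        f = tmp_path / "a.xyz"
        f.write_text("0 0 1\n1.5 2.5 3.5\n2 2 2\n")
        pts = read_xyz(f)
        assert pts.shape == (3, 3)
        assert pts[1, 2] == 3.5

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        pts = rng.uniform(-5, 5, (200, 3))
        f = tmp_path / "cloud.xyz"
        write_xyz(pts, f)
        back = read_xyz(f)
        assert back.shape == pts.shape
        assert np.allclose(back, pts, atol=5e-7)  # 6 decimal places

    def test_malformed_line_rejected_with_count(self, tmp_path, caplog):
        f = tmp_path / "bad.xyz"
        f.write_text("0 0 0\nnot a point\n1 1 1\n2 2\n")
        with caplog.at_level("WARNING"):
            pts = read_xyz(f)
        assert len(pts) == 2
        assert "2 malformed" in caplog.text

    def test_unknown_format_and_missing_file(self, tmp_path):
        f = tmp_path / "a.xyz"
        f.write_text("0 0 0\n")
        with pytest.raises(FormatError):
            read_pointcloud(f, format="ply")
        with pytest.raises(IOError):
            read_pointcloud(tmp_path / "missing.xyz")


class TestClip:
    def test_identity_when_box_covers_all(self, rng):
        pts = rng.uniform(0, 1, (50, 3))
        out = clip_to_extent(pts, (-1, -1, 2, 2))
        assert np.array_equal(out, pts)

    def test_half_open_boundaries(self):
        pts = np.array([[0.0, 0.0, 1.0], [1.0, 0.5, 1.0], [0.5, 1.0, 1.0]])
        out = clip_to_extent(pts, (0, 0, 1, 1))
        # points exactly on the upper boundary are excluded, lower included
        assert len(out) == 1 and np.array_equal(out[0], pts[0])

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 2, (500, 3))
        box = (0.3, 0.1, 1.2, 1.7)
        out = clip_to_extent(pts, box)
        brute = np.array(
            [p for p in pts if box[0] <= p[0] < box[2] and box[1] <= p[1] < box[3]]
        )
        assert np.array_equal(out, brute)


class TestDenoise:
    def test_regular_cluster_untouched(self):
        # a perfectly regular grid has identical neighbor distances everywhere
        g = np.arange(5, dtype=float)
        pts = np.array([[x, y, z] for x in g for y in g for z in g])
        assert np.array_equal(denoise(pts, 5, 3.0), pts)

    def test_distant_outlier_removed(self, rng):
        cluster = rng.normal(0, 0.05, (60, 3))
        outlier = np.array([[10.0, 10.0, 10.0]])
        out = denoise(np.vstack([cluster, outlier]), k_neighbors=5, sd_multiplier=2.0)
        assert len(out) == 60
        assert not (out == 10.0).any()

    def test_never_grows(self, rng):
        pts = rng.uniform(0, 1, (200, 3))
        assert len(denoise(pts)) <= len(pts)

    def test_small_cloud_returned_unchanged(self, rng, caplog):
        pts = rng.uniform(0, 1, (5, 3))
        with caplog.at_level("WARNING"):
            out = denoise(pts, k_neighbors=10)
        assert np.array_equal(out, pts)

    def test_commutes_with_clip_for_interior_outlier(self, rng):
        # outlier well inside the clip box: order of clip and denoise is moot
        cluster = rng.normal(0.5, 0.02, (80, 3)) + [0.5, 0.5, 0]
        outlier = np.array([[1.0, 1.0, 5.0]])
        pts = np.vstack([cluster, outlier])
        box = (0, 0, 2, 2)
        a = denoise(clip_to_extent(pts, box), 5, 2.0)
        b = clip_to_extent(denoise(pts, 5, 2.0), box)
        assert np.array_equal(np.sort(a, axis=0), np.sort(b, axis=0))


class TestGroundFilter:
    def test_flat_ground_elevation_recovered(self, rng):
        # dense enough that every 0.5 m cell sees at least one ground return
        ground = np.column_stack([rng.uniform(0, 4, 2000), rng.uniform(0, 4, 2000), np.full(2000, 10.0)])
        canopy = np.column_stack([rng.uniform(0, 4, 300), rng.uniform(0, 4, 300), rng.uniform(10.4, 11, 300)])
        mask, model = filter_ground(np.vstack([ground, canopy]), cell_size=0.5, z_tolerance=0.05)
        assert np.allclose(model.elevation, 10.0)
        assert mask[:2000].all() and not mask[2000:].any()

    def test_tilted_plane_tracked_within_cell_slope(self, rng):
        x = rng.uniform(0, 10, 2000)
        y = rng.uniform(0, 10, 2000)
        z = 10 + 0.01 * x
        _, model = filter_ground(np.column_stack([x, y, z]), cell_size=0.5)
        xs = model.x0 + (np.arange(model.elevation.shape[1]) + 0.5) * model.cell_size
        expected = 10 + 0.01 * xs
        # grid-minimum seeding biases each cell toward its low edge: one cell of slope
        assert np.abs(model.elevation - expected[None, :]).max() <= 0.01 * 0.5 + 1e-9

    def test_synthetic_labels_recovered(self, rng):
        n_g, n_c = 1000, 800
        ground = np.column_stack([rng.uniform(0, 6, n_g), rng.uniform(0, 6, n_g), rng.normal(5.0, 0.01, n_g)])
        canopy = np.column_stack([rng.uniform(0, 6, n_c), rng.uniform(0, 6, n_c), rng.uniform(5.3, 6.2, n_c)])
        mask, _ = filter_ground(np.vstack([ground, canopy]))
        truth = np.r_[np.ones(n_g, bool), np.zeros(n_c, bool)]
        agreement = (mask == truth).mean()
        assert agreement >= 0.99

    def test_empty_cloud_rejected(self):
        with pytest.raises(CanoheightError):
            filter_ground(np.empty((0, 3)))


class TestNormalize:
    def test_flat_ground_heights(self, rng):
        base = np.column_stack([rng.uniform(0, 2, 300), rng.uniform(0, 2, 300), np.full(300, 10.0)])
        _, model = filter_ground(base, cell_size=0.5)
        pts = np.array([[1.0, 1.0, 10.5], [0.5, 0.5, 10.0]])
        out = normalize(pts, model)
        assert out[0, 2] == pytest.approx(0.5)
        assert out[1, 2] == pytest.approx(0.0)

    def test_ground_only_cloud_normalizes_to_zero(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 3, 500), rng.uniform(0, 3, 500), rng.normal(7.0, 0.005, 500)]
        )
        _, model = filter_ground(pts, cell_size=0.5, z_tolerance=0.05)
        out = normalize(pts, model)
        assert (out[:, 2] <= 0.05).all()

    def test_small_negatives_clamped(self, rng):
        base = np.column_stack([rng.uniform(0, 1, 100), rng.uniform(0, 1, 100), np.zeros(100)])
        _, model = filter_ground(base)
        out = normalize(np.array([[0.5, 0.5, -0.01]]), model)
        assert out[0, 2] == 0.0


class TestMinHeightFilter:
    def test_zero_threshold_is_identity(self, rng):
        pts = np.abs(rng.uniform(0, 1, (50, 3)))
        assert np.array_equal(apply_min_height_filter(pts, 0.0), pts)

    def test_boundary_inclusive(self):
        pts = np.array([[0, 0, 0.1], [0, 0, 0.28], [0, 0, 0.5]])
        out = apply_min_height_filter(pts, 0.28)
        assert sorted(out[:, 2]) == [0.28, 0.5]

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1, (100, 3))
        out = apply_min_height_filter(pts, 0.4)
        assert len(out) == int((pts[:, 2] >= 0.4).sum())


class TestExtractPlots:
    def _map(self):
        return pd.DataFrame(
            {
                "plot_id": ["A", "B"],
                "x0": [0.0, 1.5],
                "y0": [0.0, 0.0],
                "x1": [1.0, 2.5],
                "y1": [1.0, 1.0],
            }
        )

    def test_assignment_and_spacing(self):
        pts = np.array([[0.5, 0.5, 1.0], [1.2, 0.5, 1.0], [2.0, 0.5, 1.0]])
        out = extract_plots(pts, self._map())
        assert len(out["A"]) == 1 and len(out["B"]) == 1  # middle point is in the alley
        assert sum(len(c) for c in out.values()) <= len(pts)

    def test_single_plot_covering_everything(self, rng):
        pts = rng.uniform(0, 1, (100, 3))
        out = extract_plots(pts, pd.DataFrame({"plot_id": ["P"], "x0": [0], "y0": [0], "x1": [1], "y1": [1]}))
        assert len(out["P"]) == 100

    def test_overlapping_map_rejected(self):
        bad = pd.DataFrame(
            {"plot_id": ["A", "B"], "x0": [0, 0.5], "y0": [0, 0], "x1": [1, 1.5], "y1": [1, 1]}
        )
        with pytest.raises(ConfigError):
            extract_plots(np.empty((0, 3)), bad)

    def test_empty_plots_reported_not_dropped(self, caplog):
        pts = np.array([[0.5, 0.5, 1.0]])
        with caplog.at_level("WARNING"):
            out = extract_plots(pts, self._map())
        assert "B" in out and len(out["B"]) == 0
        assert "zero points" in caplog.text


def test_noiseless_extraction_recovers_truth_exactly():
    """Zero noise + flat ground: per-plot max equals the true height exactly."""
    surf = synthesize_surface(0.73, unevenness=0.0, cover_fraction=1.0, seed=21)
    sensor = SensorModel("TLS", 3000.0, noise_sd=0.0, penetration=0.6)
    pts = sample_pointcloud(surf, sensor, seed=21)
    plot_map = pd.DataFrame({"plot_id": ["P"], "x0": [0], "y0": [0], "x1": [1], "y1": [1]})
    clouds = extract_plots(pts, plot_map)
    assert clouds["P"].z.max() == 0.73
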