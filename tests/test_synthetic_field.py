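"""Tests of the synthetic trial generator: layout, truth model, sensors."""

import math

import numpy as np
import pytest

from canoheight.errors import InvalidDesignError, InvalidParameterError
from canoheight.synthetic_field import (
    FMObservationModel,
    SensorModel,
    TrueCanopy,
    default_sensors,
    generate_design,
    gls_max_detectable,
    sample_pointcloud,
    simulate_fm,
    simulate_lai,
    simulate_true_heights,
    synthesize_surface,
)

STAGE_MEANS = {"jointing": 0.55, "heading": 0.72, "flowering": 0.85, "maturity": 0.82}


class TestDesign:
    @pytest.mark.parametrize(
        "g,e,r,expected", [(120, 2, 2, 480), (1, 1, 1, 1), (5, 2, 3, 30)]
    )
    def test_plot_count(self, g, e, r, expected):
        design = generate_design(g=g, e=e, r_reps=r)
        assert len(design.plots) == expected
        assert design.n_plots == expected

    def test_grid_pitch_and_boxes(self):
        design = generate_design(g=4, e=2, r_reps=2, plot_side=1.0, plot_spacing=0.5)
        plots = design.plots.sort_values(["row", "col"])
        first_row = plots[plots["row"] == 0]
        xs = np.sort(first_row["x0"].to_numpy())
        assert np.allclose(np.diff(xs), 1.5)  # pitch = side + spacing
        assert np.allclose(plots["x1"] - plots["x0"], 1.0)

    def test_balanced_metadata(self):
        design = generate_design(g=10, e=2, r_reps=2)
        counts = design.plots.groupby(["genotype", "treatment"]).size()
        assert (counts == 2).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_design(g=0)

    def test_seeded_determinism(self):
        a = generate_design(g=8, seed=3).plots
        b = generate_design(g=8, seed=3).plots
        c = generate_design(g=8, seed=4).plots
        assert a.equals(b)
        assert not a.equals(c)


class TestTrueHeights:
    def test_zero_variances_give_stage_means(self):
        design = generate_design(g=4, e=2, r_reps=2)
        truth = simulate_true_heights(design, STAGE_MEANS, 0, 0, 0, 0, seed=1)
        for stage, mu in STAGE_MEANS.items():
            assert np.allclose(truth.loc[truth["stage"] == stage, "true_max_height"], mu)

    def test_monotone_stage_means_monotone_heights(self):
        design = generate_design(g=3, e=1, r_reps=1, stages=("a", "b", "c"))
        truth = simulate_true_heights(
            design, {"a": 0.4, "b": 0.6, "c": 0.9}, 0.001, 0, 0.0005, 0, seed=2
        )
        wide = truth.pivot(index="plot_id", columns="stage", values="true_max_height")
        assert (wide["a"] <= wide["b"]).all() and (wide["b"] <= wide["c"]).all()

    def test_effects_shared_across_replicates(self):
        design = generate_design(g=5, e=2, r_reps=3)
        truth = simulate_true_heights(design, STAGE_MEANS, 0.01, 0.002, 0.002, 0.0, seed=5)
        one = truth[truth["stage"] == "heading"]
        # zero residual variance: replicates of a genotype x treatment agree exactly
        spread = one.groupby(["genotype", "treatment"])["true_max_height"].agg(np.ptp)
        assert np.allclose(spread, 0.0)

    def test_genotype_variance_monte_carlo(self):
        # empirical variance of genotype effects approximates var_G
        design = generate_design(g=20, e=1, r_reps=1, stages=("s",))
        effects = []
        for seed in range(200):
            truth = simulate_true_heights(design, {"s": 0.7}, 0.01, 0, 0, 0, seed=seed)
            effects.extend(truth["true_max_height"] - 0.7)
        assert np.var(effects) == pytest.approx(0.01, rel=0.15)

    def test_negative_variance_rejected(self):
        design = generate_design(g=2)
        with pytest.raises(InvalidParameterError):
            simulate_true_heights(design, STAGE_MEANS, -0.1, 0, 0, 0)


class TestSurface:
    def test_max_equals_target_exactly(self):
        for seed in range(5):
            surf = synthesize_surface(0.83, unevenness=0.4, cover_fraction=0.8, seed=seed)
            assert surf.grid.max() == 0.83
            assert (surf.grid >= 0).all()

    def test_zero_unevenness_constant_over_cover(self):
        surf = synthesize_surface(0.6, unevenness=0.0, cover_fraction=0.7, seed=1)
        covered = surf.grid[surf.grid > 0]
        assert np.allclose(covered, 0.6)

    def test_unevenness_increases_spatial_variance(self):
        flat = synthesize_surface(0.8, unevenness=0.0, cover_fraction=0.9, seed=2)
        rough = synthesize_surface(0.8, unevenness=0.3, cover_fraction=0.9, seed=2)
        assert rough.grid[rough.grid > 0].var() > flat.grid[flat.grid > 0].var()

    @pytest.mark.parametrize("target", [0.4, 0.7, 0.95])
    def test_cover_fraction_approximate(self, target):
        surf = synthesize_surface(0.8, unevenness=0.2, cover_fraction=target, seed=3)
        assert surf.realized_cover_fraction == pytest.approx(target, abs=0.12)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthesize_surface(0.0)


class TestPointClouds:
    def test_noiseless_max_bounded_by_truth(self):
        surf = synthesize_surface(0.75, cover_fraction=1.0, unevenness=0.0, seed=4)
        sensor = SensorModel("TLS", 2000.0, noise_sd=0.0, penetration=0.5)
        pts = sample_pointcloud(surf, sensor, seed=4)
        assert pts[:, 2].max() <= 0.75
        # with a fully covered constant surface the top is certainly sampled
        assert pts[:, 2].max() == 0.75

    def test_gls_detection_window(self):
        surf = synthesize_surface(1.0, cover_fraction=0.9, unevenness=0.3, seed=5)
        gls = default_sensors()["GLS"]
        pts = sample_pointcloud(surf, gls, seed=5)
        assert pts[:, 2].min() >= 0.28
        assert pts[:, 2].max() <= 0.82

    def test_poisson_point_count(self):
        surf = synthesize_surface(0.7, cover_fraction=0.9, seed=6)
        sensor = SensorModel("TLS", 1000.0, noise_sd=0.0, penetration=0.3)
        counts = [
            len(sample_pointcloud(surf, sensor, include_ground=True, seed=s))
            for s in range(200)
        ]
        # mean of 200 Poisson(1000) draws within its 99% interval
        half_width = 2.576 * math.sqrt(1000 / 200)
        assert abs(np.mean(counts) - 1000) < half_width

    def test_seeded_determinism(self):
        surf = synthesize_surface(0.7, seed=7)
        sensor = default_sensors()["BLS"]
        a = sample_pointcloud(surf, sensor, seed=9)
        b = sample_pointcloud(surf, sensor, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_sensor_rejected(self):
        with pytest.raises(InvalidParameterError):
            SensorModel("X", -1.0, 0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            SensorModel("X", 1.0, 0.0, penetration=1.5)


class TestFieldMeasurement:
    def test_full_window_no_noise_is_exact(self):
        surf = synthesize_surface(0.66, unevenness=0.3, cover_fraction=0.9, seed=8)
        fm = simulate_fm(surf, FMObservationModel(k_locations=1, window_side=1.0, observer_sd=0.0))
        assert fm == pytest.approx(0.66, abs=1e-12)

    def test_windowed_mean_underestimates_truth(self):
        surf = synthesize_surface(0.8, unevenness=0.4, cover_fraction=0.8, seed=9)
        model = FMObservationModel(k_locations=3, window_side=0.2, observer_sd=0.0)
        readings = [simulate_fm(surf, model, seed=s) for s in range(500)]
        assert np.mean(readings) <= 0.8
        assert all(r <= 0.8 + 1e-12 for r in readings)

    def test_window_larger_than_plot_rejected(self):
        surf = synthesize_surface(0.5, seed=10)
        with pytest.raises(InvalidParameterError):
            simulate_fm(surf, FMObservationModel(window_side=2.0))


class TestLAI:
    def test_arithmetic(self):
        surf = synthesize_surface(1.0, unevenness=0.0, cover_fraction=1.0, seed=11)
        lai = simulate_lai(surf, alpha=4.0, lai_noise_sd=0.0)
        assert lai == pytest.approx(4.0 * surf.realized_cover_fraction, abs=1e-9)

    def test_zero_height_zero_lai(self):
        bare = TrueCanopy("p", "s", 1.0, np.zeros((10, 10)), 0.1, 0.0, 0.0)
        bare.true_max_height = 0.0
        assert simulate_lai(bare, lai_noise_sd=0.0) == 0.0

    def test_positive_correlation_with_height(self):
        heights = np.linspace(0.3, 1.2, 60)
        lais = [
            simulate_lai(
                synthesize_surface(h, cover_fraction=0.85, seed=i, plot_id=f"p{i}"),
                lai_noise_sd=0.2,
                seed=i,
            )
            for i, h in enumerate(heights)
        ]
        assert np.corrcoef(heights, lais)[0, 1] > 0.5


def test_gls_ceiling_arithmetic():
    # 1.5 m gantry scans 1.1 m downward; the lowest 0.28 m is filtered out
    assert gls_max_detectable() == pytest.approx(0.82)
    assert gls_max_detectable(1.0, 0.3) == pytest.approx(0.70)
    with pytest.raises(InvalidParameterError):
        gls_max_detectable(0.2, 0.3)
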