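"""Designed generator experiments exercising the full analysis chain.

Each function here runs the forward model under a stated condition and
measures what the analysis recovers — the package's own validation
experiments, reused by the test suite and by ``scripts/acceptance.py``:

* :func:`h2_recovery` — known variance components in, heritability out;
* :func:`truncation_bias` — a tall canopy against the gantry scanner's
  0.82 m ceiling;
* :func:`fm_error_injection` — gross ruler errors planted in known plots,
  recovered by the set-intersection attribution;
* :func:`headline_run` — the full default trial and the qualitative
  orderings it produces.

Problem sizes are chosen for a desk machine: the heritability recovery uses
a single growth stage observed by TLS at 500 pts/m^2 with the statistical
denoiser off (the generator produces no gross outliers) and a 2 cm surface
raster, which leaves the recovered components indistinguishable from the
full-resolution settings at far lower cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accuracy_compare import bias as bias_stat
from .config import config_from_dict
from .error_attribution import attribution_report
from .height_metrics import compute_height_metric, HeightMetricSpec
from .heritability import h2_for_cells
from .pipeline import stage_heights, stage_prep, stage_simulate, run as run_pipeline
from .pointcloud_prep import extract_plots, filter_ground, normalize
from .synthetic_field import default_sensors, generate_design, simulate_field

__all__ = ["h2_recovery", "truncation_bias", "fm_error_injection", "headline_run"]


def _tls_height_table(
    seed: int,
    g: int = 120,
    var_G: float = 0.010,
    var_GE: float = 0.002,
    var_eps: float = 0.004,
    metric: str = "H99",
    density: float = 500.0,
) -> pd.DataFrame:
    """Generator → prep → metric for one seed; TLS only, one growth stage."""
    design = generate_design(g=g, e=2, r_reps=2, stages=("heading",), seed=seed)
    sensors = {"TLS": default_sensors(density_scale=1e-9, density_floor=density)["TLS"]}
    sim = simulate_field(
        design,
        {"heading": 0.72},
        sensors=sensors,
        var_G=var_G,
        var_E=0.002,
        var_GE=var_GE,
        var_eps=var_eps,
        resolution=0.02,
        seed=seed,
    )
    pts = sim.clouds[("TLS", "heading")]
    _, ground = filter_ground(pts)
    pts = normalize(pts, ground)
    clouds = extract_plots(pts, design.plots, sensor="TLS", stage="heading")
    spec = HeightMetricSpec.from_name(metric)
    heights = {pid: compute_height_metric(c.z, spec) for pid, c in clouds.items()}
    table = sim.truth.copy()
    table["value"] = table["plot_id"].map(heights)
    return table


def h2_recovery(
    n_seeds: int = 50,
    seed0: int = 0,
    var_G: float = 0.010,
    var_GE: float = 0.002,
    var_eps: float = 0.004,
) -> dict:
    """Recover broad-sense heritability through the full sensing chain.

    The implied truth for the default components is
    ``H2 = var_G / (var_G + var_GE/e + var_eps/(r e)) = 0.8333`` with
    e = r = 2.  Each seed simulates the trial, processes the TLS cloud to
    plot heights and estimates H2 from the printed closed forms; the mean
    over seeds is reported.
    """
    h2_true = var_G / (var_G + var_GE / 2 + var_eps / 4)
    estimates = []
    estimates_effect_sum = []
    for i in range(n_seeds):
        table = _tls_height_table(seed0 + i, var_G=var_G, var_GE=var_GE, var_eps=var_eps)
        cells = table.dropna(subset=["value"])
        # the EMS-corrected components estimate the *generating* variances,
        # which is what a recovery experiment targets; the effect-sum forms
        # estimate the genotype-mean variance and are reported alongside
        estimates.append(h2_for_cells(cells, ems_correction=True).H2)
        estimates_effect_sum.append(h2_for_cells(cells).H2)
    return {
        "h2_true": h2_true,
        "h2_mean": float(np.mean(estimates)),
        "h2_sd": float(np.std(estimates)),
        "h2_mean_effect_sum": float(np.mean(estimates_effect_sum)),
        "n_seeds": n_seeds,
        "estimates": estimates,
    }


def h2_noiseless_limit(seed: int = 0) -> float:
    """H2 of a noise-free trial: no interaction, no residual, exact surfaces.

    A flat closed canopy (unevenness 0, full cover), a noise-free sensor and
    known flat ground give every replicate the identical height, so the
    estimate must be exactly 1.
    """
    from .synthetic_field import SensorModel, sample_pointcloud, synthesize_surface

    design = generate_design(g=20, e=2, r_reps=2, stages=("heading",), seed=seed)
    sensor = SensorModel("TLS", 500.0, noise_sd=0.0, penetration=0.5)
    rows = []
    from .heritability import h2_for_cells as _h2

    # genotype effects only; replicates share the exact same true height
    rng_heights = {gn: 0.7 + 0.01 * i for i, gn in enumerate(sorted(design.plots["genotype"].unique()))}
    for rec in design.plots.itertuples(index=False):
        h = rng_heights[rec.genotype]
        surf = synthesize_surface(
            h, unevenness=0.0, cover_fraction=1.0, resolution=0.02,
            seed=seed, plot_id=rec.plot_id, stage="heading",
        )
        pts = sample_pointcloud(surf, sensor, seed=seed)
        rows.append(
            {
                "genotype": rec.genotype,
                "treatment": rec.treatment,
                "replicate": rec.replicate,
                "value": float(pts[:, 2].max()),
            }
        )
    return _h2(pd.DataFrame(rows)).H2


def truncation_bias(seed: int = 0, g: int = 60, stage_mean: float = 0.9) -> dict:
    """Bias of GLS vs TLS against FM when canopies exceed the GLS ceiling.

    A single tall stage puts a substantial share of plots above 0.82 m; GLS
    heights saturate there while TLS tracks the canopy, so the GLS bias is
    negative and the TLS bias stays near zero.  Heights use H99 for both
    sensors and NO eligibility screening — the point is to look at the
    saturated plots.
    """
    cfg = config_from_dict(
        {
            "simulation": {
                "g": g,
                "stages": ["tall"],
                "stage_means": {"tall": stage_mean},
                "sensor_names": ["TLS", "GLS"],
            },
            "prep": {"run_denoise": False},
        }
    )
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as td:
        sim = stage_simulate(cfg, Path(td), seed)
        clouds = stage_prep(cfg, sim, Path(td))
    spec = HeightMetricSpec.from_name("H99")
    table = sim.truth.set_index("plot_id")
    out = {}
    for sensor in ("TLS", "GLS"):
        heights = {
            pid: compute_height_metric(c.z, spec)
            for pid, c in clouds[(sensor, "tall")].items()
            if len(c)
        }
        joined = table.join(pd.Series(heights, name="h"), how="inner").dropna(subset=["h"])
        out[f"{sensor.lower()}_bias_m"] = bias_stat(joined["fm_height"], joined["h"])
        out[f"{sensor.lower()}_n"] = len(joined)
    out["share_above_ceiling"] = float((sim.truth["true_max_height"] > 0.82).mean())
    return out


def fm_error_injection(
    seed: int = 0,
    n_injected: int = 10,
    error_fraction: float = 0.5,
    g: int = 40,
) -> dict:
    """Plant gross ruler errors in known plots and measure attribution recall.

    All sensors observe the canopy accurately; ``n_injected`` eligible plots
    get their FM reading inflated/deflated by ``error_fraction`` (alternating
    sign).  The strict intersection rule should place those plots in
    Error_FM; recall is the recovered share.
    """
    cfg = config_from_dict(
        {
            "simulation": {"g": g, "stages": ["heading"], "stage_means": {"heading": 0.72}},
            "prep": {"run_denoise": False},
        }
    )
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as td:
        out_dir = Path(td)
        sim = stage_simulate(cfg, out_dir, seed)
        clouds = stage_prep(cfg, sim, out_dir)
        table = stage_heights(cfg, sim, clouds, out_dir)

    # keep the injected reading below the GLS ceiling even after inflation,
    # so the corrupted plot stays inside the four-sensor attribution universe
    eligible = table[(table["FM"] > 0) & (table["FM"] * (1 + error_fraction) < 0.80)].dropna(
        subset=["TLS", "BLS", "GLS", "DAP"]
    )
    rng = np.random.default_rng(seed + 1)
    chosen = rng.choice(eligible.index.to_numpy(), size=n_injected, replace=False)
    table = table.copy()
    signs = np.where(np.arange(n_injected) % 2 == 0, 1.0, -1.0)
    table.loc[chosen, "FM"] = table.loc[chosen, "FM"] * (1.0 + signs * error_fraction)

    strict, _, _ = attribution_report(table, tau=0.2)
    injected_ids = {
        f"{table.loc[i, 'plot_id']}@{table.loc[i, 'stage']}" for i in chosen
    }
    recovered = injected_ids & strict.error_fm
    false_alarms = strict.error_fm - injected_ids
    return {
        "recall": len(recovered) / n_injected,
        "n_injected": n_injected,
        "n_error_fm": len(strict.error_fm),
        "n_false_alarms": len(false_alarms),
    }


def headline_run(seed: int = 0, out_dir=None, g: int = 120) -> dict:
    """Full default trial; returns the qualitative headline quantities.

    The orderings mirror the multi-sensor study design: cross-sensor
    correlations exceed sensor-vs-FM correlations when ruler error dominates
    sensor error; stratifying by measured height shrinks correlations
    (range restriction); 3D-sensing heritability is at least the ruler's.
    """
    import tempfile
    from pathlib import Path

    cfg = config_from_dict({"simulation": {"g": g}})
    td = None
    if out_dir is None:
        td = tempfile.TemporaryDirectory()
        out_dir = td.name
    try:
        run_pipeline(cfg, out_dir, seed=seed)
        out = Path(out_dir)
        matrix = pd.read_csv(out / "compare" / "comparison_matrix.csv")
        h2 = pd.read_csv(out / "h2" / "heritability.csv")
    finally:
        if td is not None:
            td.cleanup()

    pooled = matrix[matrix["group"] == "all"].set_index("pairing")
    fm_rows = [p for p in pooled.index if p.endswith("vs FM")]
    cross_rows = [p for p in pooled.index if not p.endswith("vs FM")]
    tls = matrix[matrix["pairing"] == "TLS vs FM"]
    pooled_r_tls = float(tls[tls["group"] == "all"]["r"].iloc[0])
    ch_mean_r_tls = float(
        tls[(tls["group_var"] == "CH") & (tls["group"] == "Mean")]["r"].iloc[0]
    )
    h2_pooled = h2[h2["group_var"] == "pooled"].iloc[0]
    return {
        "max_fm_r": float(pooled.loc[fm_rows, "r"].max()),
        "min_cross_r": float(pooled.loc[cross_rows, "r"].min()),
        "pooled_r_tls_vs_fm": pooled_r_tls,
        "mean_ch_subgroup_r_tls_vs_fm": ch_mean_r_tls,
        "h2_fm": float(h2_pooled["FM"]),
        "h2_tls": float(h2_pooled["TLS"]),
        "gls_pooled_bias_m": float(pooled.loc["GLS vs FM", "bias"]),
        "n_observations": int(pooled.loc["TLS vs FM", "n"]),
    }
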