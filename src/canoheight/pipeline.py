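"""End-to-end orchestration: simulate → prep → heights → compare → h2 → attribute.

A run writes into a fixed directory layout::

    out/
      sim/          plot_map.csv, metadata.csv, truth.csv [, clouds/*.xyz]
      prep/         prep_summary.json
      heights/      metrics_long.csv, metric_selection.csv, plot_heights.csv
      compare/      comparison_matrix.csv, table_CH.csv, table_LAI.csv, table_GS.csv
      h2/           heritability.csv, h2_components.csv
      attribution/  residuals.csv, attribution_summary.csv, attribution_sets.json
      manifest.yaml

``heights/plot_heights.csv`` is the pipeline's central table (one row per
plot observation; FM, per-sensor selected-metric heights, LAI, metadata) and
the resume point: with ``resume=True`` the downstream stages restart from it
without re-simulating.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy_compare import (
    GroupingScheme,
    SENSOR_SOURCES,
    comparison_matrix,
    default_grouping_schemes,
)
from .config import PipelineConfig, config_to_dict
from .error_attribution import attribution_report
from .errors import CanoheightError
from .height_metrics import metrics_long_table, select_optimal_metric
from .heritability import h2_by_group
from .pointcloud_prep import (
    apply_min_height_filter,
    denoise,
    extract_plots,
    filter_ground,
    normalize,
    write_xyz,
)
from .synthetic_field import FieldSimulation, generate_design, simulate_field

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "prep", "heights", "compare", "h2", "attribute")

__all__ = ["run", "STAGE_ORDER"]


def _write_manifest(out: Path, manifest: dict) -> None:
    tmp = out / "manifest.yaml.tmp"
    tmp.write_text(yaml.safe_dump(manifest, sort_keys=False))
    tmp.replace(out / "manifest.yaml")


def _grouping_schemes(cfg: PipelineConfig) -> dict[str, GroupingScheme]:
    schemes = default_grouping_schemes(cfg.simulation.stages)
    schemes["CH"] = GroupingScheme("CH", tuple(f"CH{i+1}" for i in range(len(cfg.compare.ch_edges) - 1)),
                                   tuple(cfg.compare.ch_edges))
    schemes["LAI"] = GroupingScheme("LAI", tuple(f"LAI{i+1}" for i in range(len(cfg.compare.lai_edges) - 1)),
                                    tuple(cfg.compare.lai_edges))
    return schemes


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> FieldSimulation:
    sim_cfg = cfg.simulation
    design = generate_design(
        g=sim_cfg.g,
        e=sim_cfg.e,
        r_reps=sim_cfg.r_reps,
        stages=sim_cfg.stages,
        plot_side=sim_cfg.plot_side,
        plot_spacing=sim_cfg.plot_spacing,
        seed=seed,
    )
    sim = simulate_field(
        design,
        sim_cfg.stage_means,
        sensors=sim_cfg.sensors(),
        fm_model=sim_cfg.fm_model(),
        var_G=sim_cfg.var_G,
        var_E=sim_cfg.var_E,
        var_GE=sim_cfg.var_GE,
        var_eps=sim_cfg.var_eps,
        unevenness=sim_cfg.unevenness,
        cover_fraction=sim_cfg.cover_fraction,
        resolution=sim_cfg.resolution,
        lai_alpha=sim_cfg.lai_alpha,
        lai_noise_sd=sim_cfg.lai_noise_sd,
        terrain=sim_cfg.terrain(),
        alley_ground_fraction=sim_cfg.alley_ground_fraction,
        seed=seed,
    )
    d = out / "sim"
    d.mkdir(parents=True, exist_ok=True)
    design.plots[["plot_id", "x0", "y0", "x1", "y1"]].to_csv(d / "plot_map.csv", index=False)
    design.plots[["plot_id", "genotype", "treatment", "replicate"]].to_csv(
        d / "metadata.csv", index=False
    )
    sim.truth.to_csv(d / "truth.csv", index=False)
    if cfg.io.write_clouds:
        cdir = d / "clouds"
        cdir.mkdir(exist_ok=True)
        for (sensor, stage), pts in sim.clouds.items():
            write_xyz(pts, cdir / f"{sensor}_{stage}.xyz")
    return sim


def stage_prep(cfg: PipelineConfig, sim: FieldSimulation, out: Path) -> dict:
    """Per (sensor, stage): denoise, ground-filter, normalize, extract plots.

    GLS clouds arrive already normalized and ground-free (the gantry software
    filters the lowest 0.28 m during collection); for them only the height
    threshold is (re-)asserted before plot extraction.
    """
    prep_cfg = cfg.prep
    plot_map = sim.design.plots[["plot_id", "x0", "y0", "x1", "y1"]]
    plot_clouds: dict[tuple[str, str], dict] = {}
    summary = []
    for (sensor, stage), pts in sim.clouds.items():
        n_raw = len(pts)
        model = sim.sensors[sensor]
        if prep_cfg.run_denoise and n_raw:
            pts = denoise(pts, prep_cfg.denoise_k, prep_cfg.denoise_sd)
        if model.normalized_output:
            pts = apply_min_height_filter(pts, model.min_detectable_z)
        elif prep_cfg.assume_flat_ground:
            pts = np.column_stack([pts[:, 0], pts[:, 1], np.maximum(pts[:, 2], 0.0)])
        else:
            _, ground = filter_ground(pts, prep_cfg.cell_size, prep_cfg.z_tolerance)
            pts = normalize(pts, ground)
        clouds = extract_plots(pts, plot_map, sensor=sensor, stage=stage)
        plot_clouds[(sensor, stage)] = clouds
        summary.append(
            {
                "sensor": sensor,
                "stage": stage,
                "n_raw": int(n_raw),
                "n_after_prep": int(len(pts)),
                "n_in_plots": int(sum(len(c) for c in clouds.values())),
                "n_empty_plots": int(sum(1 for c in clouds.values() if len(c) == 0)),
            }
        )
    d = out / "prep"
    d.mkdir(parents=True, exist_ok=True)
    (d / "prep_summary.json").write_text(json.dumps(summary, indent=2))
    return plot_clouds


def stage_heights(cfg: PipelineConfig, sim: FieldSimulation, plot_clouds: dict, out: Path) -> pd.DataFrame:
    method = cfg.metrics.quantile_method
    long_parts = []
    for (sensor, stage), clouds in plot_clouds.items():
        long_parts.append(metrics_long_table(clouds, sensor, stage, method=method))
    long_table = pd.concat(long_parts, ignore_index=True)

    fm = sim.truth[["plot_id", "stage", "fm_height"]]
    long_table = long_table.merge(fm, on=["plot_id", "stage"], how="left")

    selections = {}
    score_frames = []
    for sensor in sorted({s for s, _ in plot_clouds}):
        sub = long_table[long_table["source"] == sensor].copy()
        if sensor == "GLS":  # selection mirrors the eligibility rule used downstream
            sub = sub[sub["fm_height"] < cfg.compare.resolved_ceiling(cfg.simulation)]
        spec, scores = select_optimal_metric(sub, sensor)
        selections[sensor] = spec.name
        scores = scores.assign(source=sensor, selected=scores["metric"] == spec.name)
        score_frames.append(scores)

    wide = long_table.pivot_table(
        index=["plot_id", "stage"], columns=["source", "metric"], values="height_m"
    )
    table = sim.truth.set_index(["plot_id", "stage"])[
        ["genotype", "treatment", "replicate", "true_max_height", "cover_fraction", "fm_height", "lai"]
    ].copy()
    table["FM"] = table["fm_height"]
    for sensor, metric in selections.items():
        table[sensor] = wide[(sensor, metric)]
    table = table.reset_index().drop(columns="fm_height")

    d = out / "heights"
    d.mkdir(parents=True, exist_ok=True)
    long_table.to_csv(d / "metrics_long.csv", index=False)
    pd.concat(score_frames, ignore_index=True).to_csv(d / "metric_selection.csv", index=False)
    # %.17g survives a CSV round trip bit for bit: the resume point must
    # reproduce downstream stages exactly
    table.to_csv(d / "plot_heights.csv", index=False, float_format="%.17g")
    return table


def stage_compare(cfg: PipelineConfig, table: pd.DataFrame, out: Path) -> pd.DataFrame:
    schemes = _grouping_schemes(cfg)
    matrix = comparison_matrix(
        table, schemes, gls_ceiling=cfg.compare.resolved_ceiling(cfg.simulation)
    )
    d = out / "compare"
    d.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(d / "comparison_matrix.csv", index=False)
    for var in schemes:
        sub = matrix[matrix["group_var"].isin([var, "pooled"])]
        piv = sub.pivot_table(index="group", columns="pairing", values="r", sort=False)
        piv.to_csv(d / f"table_{var}.csv")
    return matrix


def stage_h2(cfg: PipelineConfig, table: pd.DataFrame, out: Path) -> pd.DataFrame:
    schemes = _grouping_schemes(cfg)
    sources = ["FM"] + [s for s in SENSOR_SOURCES if s in table.columns]
    ceiling = cfg.compare.resolved_ceiling(cfg.simulation)
    rows = []
    comp_rows = []
    for var, scheme in [("pooled", None)] + list(schemes.items()):
        group_names = ["all"] if scheme is None else list(scheme.names)
        per_source = {}
        for source in sources:
            restrict = True if cfg.h2.restrict_all_sources else None
            per_source[source] = h2_by_group(
                table,
                source,
                scheme,
                gls_ceiling=ceiling,
                restrict_to_eligible=restrict,
                min_varieties=cfg.h2.min_varieties,
                ems_correction=cfg.h2.ems_correction,
            )
        for gname in group_names:
            row = {"group_var": var, "group": gname}
            for source in sources:
                res = per_source[source][gname]
                row[source] = res.H2
                comp = res.components
                comp_rows.append(
                    {
                        "group_var": var,
                        "group": gname,
                        "source": source,
                        "H2": res.H2,
                        "n_varieties_used": res.n_varieties_used,
                        "sigma2_G": comp.sigma2_G if comp else float("nan"),
                        "sigma2_E": comp.sigma2_E if comp else float("nan"),
                        "sigma2_GE": comp.sigma2_GE if comp else float("nan"),
                        "sigma2_eps": comp.sigma2_eps if comp else float("nan"),
                    }
                )
            rows.append(row)
        if scheme is not None:  # unweighted mean across defined groups
            mean_row = {"group_var": var, "group": "Mean"}
            for source in sources:
                vals = [r[source] for r in rows if r["group_var"] == var
                        and r["group"] != "Mean" and np.isfinite(r[source])]
                mean_row[source] = float(np.mean(vals)) if vals else float("nan")
            rows.append(mean_row)

    h2_table = pd.DataFrame(rows)
    d = out / "h2"
    d.mkdir(parents=True, exist_ok=True)
    h2_table.to_csv(d / "heritability.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(d / "h2_components.csv", index=False)
    return h2_table


def stage_attribute(cfg: PipelineConfig, table: pd.DataFrame, out: Path):
    strict, relaxed, residuals = attribution_report(
        table,
        tau=cfg.attribution.tau,
        relaxed_m=cfg.attribution.relaxed_m,
        gls_ceiling=cfg.compare.resolved_ceiling(cfg.simulation),
    )
    d = out / "attribution"
    d.mkdir(parents=True, exist_ok=True)
    residuals.to_csv(d / "residuals.csv", index=False)
    summary = [
        {"source": a, "n_suspicious": len(strict.suspicious[a]), "n_attributed": len(strict.error_by_source[a])}
        for a in strict.suspicious
    ]
    summary.append({"source": "FM", "n_suspicious": len(strict.error_fm), "n_attributed": len(strict.error_fm)})
    pd.DataFrame(summary).to_csv(d / "attribution_summary.csv", index=False)
    sets = {
        "tau": strict.tau,
        "strict": {
            "error_fm": sorted(strict.error_fm),
            **{f"error_{a.lower()}": sorted(s) for a, s in strict.error_by_source.items()},
        },
    }
    if relaxed is not None:
        sets["relaxed_m"] = cfg.attribution.relaxed_m
        sets["relaxed"] = {
            "error_fm": sorted(relaxed.error_fm),
            **{f"error_{a.lower()}": sorted(s) for a, s in relaxed.error_by_source.items()},
        }
    (d / "attribution_sets.json").write_text(json.dumps(sets, indent=2))
    return strict, relaxed


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run(
    cfg: PipelineConfig,
    out_dir,
    seed: int | None = None,
    resume: bool = False,
) -> Path:
    """Execute the pipeline into ``out_dir``; returns the run directory.

    ``seed`` overrides ``cfg.seed``.  With ``resume=True`` and an existing
    ``heights/plot_heights.csv``, simulation/prep/heights are skipped and the
    downstream stages recompute from that table (they are deterministic given
    it, so a resumed run matches a full run byte for byte downstream).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else int(seed)

    manifest = {
        "package": "canoheight",
        "version": __version__,
        "seed": seed,
        "config": config_to_dict(cfg),
        "stages": {},
    }

    heights_csv = out / "heights" / "plot_heights.csv"
    table: pd.DataFrame
    try:
        if resume and heights_csv.exists():
            logger.info("resuming from %s", heights_csv)
            # exact float parsing: a resumed run must match the original bitwise
            table = pd.read_csv(heights_csv, float_precision="round_trip")
            manifest["stages"]["simulate"] = {"status": "resumed"}
            manifest["stages"]["prep"] = {"status": "resumed"}
            manifest["stages"]["heights"] = {"status": "resumed"}
        else:
            t0 = time.time()
            sim = stage_simulate(cfg, out, seed)
            manifest["stages"]["simulate"] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
                "n_plots": sim.design.n_plots,
                "n_observations": len(sim.truth),
            }
            _write_manifest(out, manifest)

            t0 = time.time()
            plot_clouds = stage_prep(cfg, sim, out)
            manifest["stages"]["prep"] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            _write_manifest(out, manifest)

            t0 = time.time()
            table = stage_heights(cfg, sim, plot_clouds, out)
            manifest["stages"]["heights"] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            _write_manifest(out, manifest)

        t0 = time.time()
        stage_compare(cfg, table, out)
        manifest["stages"]["compare"] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        _write_manifest(out, manifest)

        t0 = time.time()
        stage_h2(cfg, table, out)
        manifest["stages"]["h2"] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        _write_manifest(out, manifest)

        t0 = time.time()
        stage_attribute(cfg, table, out)
        manifest["stages"]["attribute"] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        _write_manifest(out, manifest)
    except CanoheightError as exc:
        manifest["stages"]["error"] = str(exc)
        _write_manifest(out, manifest)
        raise
    return out
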