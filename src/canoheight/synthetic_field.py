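"""Synthetic multi-sensor wheat-field trial generator.

This module produces a fully specified stand-in for a plot-based field trial
observed by four 3D sensing systems — terrestrial (TLS), backpack (BLS) and
gantry (GLS) laser scanning plus digital aerial photogrammetry (DAP) — together
with ruler-style field measurements (FM) and a leaf-area-index (LAI) covariate.

The forward model is deliberately layered so that every downstream analysis
stage can be tested against known ground truth:

1. a randomized plot layout (genotype x nitrogen treatment x replicate);
2. per-plot *true* maximum canopy heights following a plain random-effects
   model ``height = stage_mean + G_i + E_j + GE_ij + eps``;
3. a crown-bump canopy *surface* whose maximum equals the true height;
4. sensor point clouds sampled from the surface with sensor-specific density,
   vertical noise, canopy penetration, tip loss and detection-range truncation
   (the gantry system drops everything below 0.28 m and cannot see above
   0.82 m above ground);
5. ruler measurements as window-maxima plus observer error, and an LAI value
   proportional to cover fraction times height.

All randomness is keyed through :func:`canoheight._seeding.spawn_rng`, so one
root seed reproduces the complete trial bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import spawn_rng
from .errors import InvalidDesignError, InvalidParameterError

__all__ = [
    "FieldDesign",
    "TrueCanopy",
    "SensorModel",
    "FMObservationModel",
    "FieldSimulation",
    "FULL_POINT_DENSITIES",
    "generate_design",
    "simulate_true_heights",
    "synthesize_surface",
    "sample_pointcloud",
    "simulate_fm",
    "simulate_lai",
    "default_sensors",
    "gls_max_detectable",
    "simulate_field",
]

#: Point densities (pts/m^2) of the four preprocessed sources at heading stage.
FULL_POINT_DENSITIES: dict[str, float] = {
    "TLS": 929_021.12,
    "BLS": 17_761.30,
    "GLS": 697_092.18,
    "DAP": 40_051.30,
}

DEFAULT_STAGES: tuple[str, ...] = ("jointing", "heading", "flowering", "maturity")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldDesign:
    """A balanced genotype x treatment x replicate plot layout.

    ``plots`` holds one row per plot with columns ``plot_id, genotype,
    treatment, replicate, x0, y0, x1, y1``.  Bounding boxes are axis aligned,
    half open ``[x0, x1) x [y0, y1)`` and laid on a regular grid with pitch
    ``plot_side + plot_spacing``.
    """

    g: int
    e: int
    r_reps: int
    stages: tuple[str, ...]
    plot_side: float
    plot_spacing: float
    seed: int
    plots: pd.DataFrame = field(repr=False)

    @property
    def n_plots(self) -> int:
        return self.g * self.e * self.r_reps

    @property
    def pitch(self) -> float:
        return self.plot_side + self.plot_spacing

    @property
    def n_cols(self) -> int:
        return int(self.plots["col"].max()) + 1

    @property
    def n_rows(self) -> int:
        return int(self.plots["row"].max()) + 1

    def field_extent(self) -> tuple[float, float]:
        """(width, height) of the bounding rectangle covering all plots and alleys."""
        return self.n_cols * self.pitch, self.n_rows * self.pitch


@dataclass
class TrueCanopy:
    """Ground-truth canopy surface of one plot at one growth stage.

    ``grid`` is height above ground (m) on a square raster of spacing
    ``resolution`` covering the plot footprint; zeros mark bare ground.
    """

    plot_id: str
    stage: str
    true_max_height: float
    grid: np.ndarray
    resolution: float
    unevenness: float
    cover_fraction: float

    @property
    def realized_cover_fraction(self) -> float:
        return float(np.mean(self.grid > 0.0))

    def heights_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Surface height at plot-local coordinates (nearest-cell lookup)."""
        n = self.grid.shape[0]
        ix = np.clip((x / self.resolution).astype(int), 0, n - 1)
        iy = np.clip((y / self.resolution).astype(int), 0, n - 1)
        return self.grid[iy, ix]


@dataclass(frozen=True)
class SensorModel:
    """Observation model of one 3D sensing system.

    Parameters
    ----------
    point_density : float
        Expected returns per m^2 over the plot footprint.
    noise_sd : float
        Gaussian ranging noise (m) added to every return's z.
    penetration : float
        Fraction of canopy returns placed inside the canopy (uniform between
        ground and the local surface) rather than on the top surface.  DAP,
        which reconstructs only the visible surface, uses 0.
    min_detectable_z, max_detectable_z : float
        Detection window in *normalized* height (m above ground); returns
        outside it are dropped.  The gantry system's integrated ground filter
        removes the lowest 0.28 m, and with a 1.1 m scan range its effective
        ceiling is 0.82 m.
    tip_loss : float
        Fraction of top-surface returns near the canopy maximum that are
        dropped — photogrammetry loses thin leaf tips.
    drops_ground : bool
        Whether bare-ground returns are removed at acquisition time (GLS).
    normalized_output : bool
        Whether the sensor emits heights above ground directly (GLS is
        normalized during collection); otherwise z is terrain + canopy.
    """

    name: str
    point_density: float
    noise_sd: float
    penetration: float
    min_detectable_z: float = -math.inf
    max_detectable_z: float = math.inf
    tip_loss: float = 0.0
    drops_ground: bool = False
    normalized_output: bool = False

    def __post_init__(self):
        if self.point_density <= 0:
            raise InvalidParameterError(f"{self.name}: point_density must be > 0")
        if not 0.0 <= self.penetration <= 1.0:
            raise InvalidParameterError(f"{self.name}: penetration must be in [0, 1]")
        if not self.min_detectable_z < self.max_detectable_z:
            raise InvalidParameterError(
                f"{self.name}: min_detectable_z must be < max_detectable_z"
            )
        if not 0.0 <= self.tip_loss < 1.0:
            raise InvalidParameterError(f"{self.name}: tip_loss must be in [0, 1)")


@dataclass(frozen=True)
class FMObservationModel:
    """Ruler-based field measurement: mean of ``k_locations`` window maxima.

    Each location is a random ``window_side`` x ``window_side`` patch of the
    plot; the observer reads the local canopy maximum with Gaussian error
    ``observer_sd`` (m), and the k readings are averaged.
    """

    k_locations: int = 3
    window_side: float = 0.3
    observer_sd: float = 0.02

    def __post_init__(self):
        if self.k_locations < 1:
            raise InvalidParameterError("k_locations must be >= 1")
        if self.window_side <= 0:
            raise InvalidParameterError("window_side must be > 0")
        if self.observer_sd < 0:
            raise InvalidParameterError("observer_sd must be >= 0")


def gls_max_detectable(scan_range: float = 1.1, ground_filter_height: float = 0.28) -> float:
    """Effective maximum canopy height of the gantry scanner.

    The sensor head scans ``scan_range`` m downward and the acquisition
    software removes the lowest ``ground_filter_height`` m, so the tallest
    canopy it can report is their difference (0.82 m with the defaults).
    """
    if scan_range <= ground_filter_height:
        raise InvalidParameterError("scan_range must exceed ground_filter_height")
    return scan_range - ground_filter_height


def default_sensors(
    density_scale: float = 2e-3,
    density_floor: float = 800.0,
    gls_ground_filter: float = 0.28,
    gls_scan_range: float = 1.1,
) -> dict[str, SensorModel]:
    """Sensor models with densities scaled down from the full-survey values.

    ``density_scale=1.0`` restores the full preprocessed densities (about
    9.3e5 pts/m^2 for TLS); the default 1e-3 keeps the relative ordering while
    making a 480-plot, 4-stage simulation tractable on one CPU.
    ``density_floor`` prevents the sparse sources from degenerating below a
    usable per-plot count at small scales.
    """

    def dens(name: str) -> float:
        return max(FULL_POINT_DENSITIES[name] * density_scale, density_floor)

    return {
        "TLS": SensorModel("TLS", dens("TLS"), noise_sd=0.003, penetration=0.7),
        "BLS": SensorModel("BLS", dens("BLS"), noise_sd=0.012, penetration=0.7),
        "GLS": SensorModel(
            "GLS",
            dens("GLS"),
            noise_sd=0.002,
            penetration=0.6,
            min_detectable_z=gls_ground_filter,
            max_detectable_z=gls_max_detectable(gls_scan_range, gls_ground_filter),
            drops_ground=True,
            normalized_output=True,
        ),
        "DAP": SensorModel("DAP", dens("DAP"), noise_sd=0.010, penetration=0.0, tip_loss=0.3),
    }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_design(
    g: int = 120,
    e: int = 2,
    r_reps: int = 2,
    stages: Sequence[str] = DEFAULT_STAGES,
    plot_side: float = 1.0,
    plot_spacing: float = 0.5,
    seed: int = 0,
) -> FieldDesign:
    """Lay out a balanced trial of ``g*e*r_reps`` plots on a regular grid.

    Treatment labels follow the trial's nitrogen levels ("N0", "N240") when
    ``e == 2``; otherwise generic "T1..Te".  Plot positions are randomized
    (seeded) across the grid, as in a randomized field design.
    """
    if g < 1 or e < 1 or r_reps < 1:
        raise InvalidDesignError(f"counts must be >= 1 (got g={g}, e={e}, r_reps={r_reps})")
    if plot_side <= 0 or plot_spacing < 0:
        raise InvalidDesignError("plot_side must be > 0 and plot_spacing >= 0")
    if len(stages) < 1:
        raise InvalidDesignError("at least one growth stage is required")

    n = g * e * r_reps
    genotypes = [f"V{i + 1:03d}" for i in range(g)]
    treatments = ["N0", "N240"] if e == 2 else [f"T{j + 1}" for j in range(e)]

    records = []
    for i, geno in enumerate(genotypes):
        for j, trt in enumerate(treatments):
            for k in range(r_reps):
                records.append((geno, trt, k + 1))

    rng = spawn_rng(seed, "design")
    order = rng.permutation(n)

    ncols = int(math.ceil(math.sqrt(n)))
    pitch = plot_side + plot_spacing
    rows = []
    for pos, idx in enumerate(order):
        geno, trt, rep = records[idx]
        col, row = pos % ncols, pos // ncols
        x0, y0 = col * pitch, row * pitch
        rows.append(
            {
                "plot_id": f"P{pos + 1:04d}",
                "genotype": geno,
                "treatment": trt,
                "replicate": rep,
                "col": col,
                "row": row,
                "x0": x0,
                "y0": y0,
                "x1": x0 + plot_side,
                "y1": y0 + plot_side,
            }
        )
    plots = pd.DataFrame(rows)
    return FieldDesign(
        g=g,
        e=e,
        r_reps=r_reps,
        stages=tuple(stages),
        plot_side=float(plot_side),
        plot_spacing=float(plot_spacing),
        seed=int(seed),
        plots=plots,
    )


def simulate_true_heights(
    design: FieldDesign,
    stage_means: Mapping[str, float],
    var_G: float,
    var_E: float,
    var_GE: float,
    var_eps: float,
    seed: int = 0,
    min_height: float = 0.01,
) -> pd.DataFrame:
    """Draw per-plot, per-stage true maximum canopy heights.

    ``height = stage_mean + G_i + E_j + GE_ij + eps`` with the four terms
    i.i.d. Gaussian.  Genotype (G), treatment (E) and interaction (GE) effects
    are drawn once and shared across replicates and stages — a genotype that
    is tall at jointing stays tall at maturity — while the residual is
    redrawn per plot and stage.  Effects are NOT re-centered within a draw;
    finite-sample deviation from zero mean is part of the model.

    Returns a tidy frame with one row per (plot, stage):
    ``plot_id, stage, genotype, treatment, replicate, true_max_height``.
    """
    for nm, v in (("var_G", var_G), ("var_E", var_E), ("var_GE", var_GE), ("var_eps", var_eps)):
        if v < 0:
            raise InvalidParameterError(f"{nm} must be >= 0 (got {v})")
    missing = [s for s in design.stages if s not in stage_means]
    if missing:
        raise InvalidParameterError(f"stage_means missing stages: {missing}")
    bad = [s for s in design.stages if stage_means[s] <= 0]
    if bad:
        raise InvalidParameterError(f"stage_means must be positive; offending stages: {bad}")

    genotypes = sorted(design.plots["genotype"].unique())
    treatments = sorted(design.plots["treatment"].unique())

    rng = spawn_rng(seed, "true-heights")
    G = dict(zip(genotypes, rng.normal(0.0, math.sqrt(var_G), len(genotypes))))
    E = dict(zip(treatments, rng.normal(0.0, math.sqrt(var_E), len(treatments))))
    GE = {
        (gn, tr): v
        for (gn, tr), v in zip(
            [(gn, tr) for gn in genotypes for tr in treatments],
            rng.normal(0.0, math.sqrt(var_GE), len(genotypes) * len(treatments)),
        )
    }

    frames = []
    for stage in design.stages:
        mu = float(stage_means[stage])
        df = design.plots[["plot_id", "genotype", "treatment", "replicate"]].copy()
        eps_rng = spawn_rng(seed, "true-heights", "eps", stage)
        eps = eps_rng.normal(0.0, math.sqrt(var_eps), len(df))
        h = (
            mu
            + df["genotype"].map(G).to_numpy()
            + df["treatment"].map(E).to_numpy()
            + np.array([GE[(gn, tr)] for gn, tr in zip(df["genotype"], df["treatment"])])
            + eps
        )
        df["stage"] = stage
        df["true_max_height"] = np.maximum(h, min_height)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["plot_id", "stage", "genotype", "treatment", "replicate", "true_max_height"]]


def synthesize_surface(
    true_max_height: float,
    unevenness: float = 0.25,
    cover_fraction: float = 0.9,
    resolution: float = 0.01,
    seed: int = 0,
    plot_side: float = 1.0,
    plot_id: str = "",
    stage: str = "",
    max_bumps: int = 4000,
) -> TrueCanopy:
    """Build a crown-bump canopy height field over one plot.

    Smooth radial bumps (paraboloid caps of random radius and peak) are
    superposed by maximum until the covered area reaches ``cover_fraction``,
    then the whole field is rescaled so its maximum equals
    ``true_max_height`` exactly.  ``unevenness`` controls both within-bump
    droop and between-bump peak spread; 0 gives a flat slab of height
    ``true_max_height`` over the covered area.
    """
    if true_max_height <= 0:
        raise InvalidParameterError("true_max_height must be > 0")
    if not 0.0 < cover_fraction <= 1.0:
        raise InvalidParameterError("cover_fraction must be in (0, 1]")
    if unevenness < 0:
        raise InvalidParameterError("unevenness must be >= 0")
    if resolution <= 0 or resolution > plot_side:
        raise InvalidParameterError("resolution must be in (0, plot_side]")

    rng = spawn_rng(seed, "surface", plot_id, stage)
    n = max(int(round(plot_side / resolution)), 1)
    grid = np.zeros((n, n))
    axis = (np.arange(n) + 0.5) * resolution

    mean_radius = 0.12 * plot_side
    target = cover_fraction * n * n
    bumps_placed = 0
    # expected fresh coverage per bump shrinks as the plot fills; place in batches
    while np.count_nonzero(grid) < target and bumps_placed < max_bumps:
        frac = np.count_nonzero(grid) / (n * n)
        remaining = max(cover_fraction - frac, 1e-3)
        area_frac = math.pi * mean_radius**2 / plot_side**2
        batch = max(int(math.ceil(-math.log(max(1 - remaining, 1e-12)) / area_frac / 4)), 1)
        batch = min(batch, 64, max_bumps - bumps_placed)
        cx = rng.uniform(0, plot_side, batch)
        cy = rng.uniform(0, plot_side, batch)
        radius = mean_radius * rng.uniform(0.6, 1.4, batch)
        peak = 1.0 + unevenness * rng.uniform(-0.5, 0.5, batch)
        for b in range(batch):
            r = radius[b]
            i0 = max(int((cy[b] - r) / resolution), 0)
            i1 = min(int((cy[b] + r) / resolution) + 2, n)
            j0 = max(int((cx[b] - r) / resolution), 0)
            j1 = min(int((cx[b] + r) / resolution) + 2, n)
            if i0 >= i1 or j0 >= j1:
                continue
            dx = axis[j0:j1] - cx[b]
            dy = axis[i0:i1] - cy[b]
            d2 = (dy[:, None] ** 2 + dx[None, :] ** 2) / r**2
            inside = d2 < 1.0
            # paraboloid cap: flat slab at unevenness 0, drooping edges otherwise
            h = peak[b] * (1.0 - unevenness * d2)
            patch = np.where(inside, h, 0.0)
            np.maximum(grid[i0:i1, j0:j1], patch, out=grid[i0:i1, j0:j1])
        bumps_placed += batch

    peak_now = grid.max()
    if peak_now <= 0:  # pragma: no cover - cover_fraction > 0 guarantees a bump
        grid[n // 2, n // 2] = 1.0
        peak_now = 1.0
    grid *= true_max_height / peak_now
    # pin the maximum exactly despite floating-point rescaling
    np.minimum(grid, true_max_height, out=grid)
    grid[np.unravel_index(np.argmax(grid), grid.shape)] = true_max_height
    return TrueCanopy(
        plot_id=plot_id,
        stage=stage,
        true_max_height=float(true_max_height),
        grid=grid,
        resolution=resolution,
        unevenness=unevenness,
        cover_fraction=cover_fraction,
    )


def sample_pointcloud(
    surface: TrueCanopy,
    sensor: SensorModel,
    include_ground: bool = True,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    terrain: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 0.0,
) -> np.ndarray:
    """Sample one sensor's returns over one plot; returns an (n, 3) array.

    The point count is Poisson(density x area).  Horizontal positions are
    uniform over the plot; each return takes the local surface height (or a
    uniform interior height for penetrating returns), gets Gaussian ranging
    noise, and is dropped if its normalized height falls outside the sensor's
    detection window.  Ground returns (cells with no canopy) are kept only if
    both ``include_ground`` and the sensor retains ground.

    ``origin`` shifts x/y into field coordinates; ``terrain`` (constant or
    callable of field x/y) is added to z unless the sensor emits normalized
    heights directly.
    """
    rng = spawn_rng(seed, "cloud", surface.plot_id, surface.stage, sensor.name)
    side = surface.grid.shape[0] * surface.resolution
    area = side * side
    n_pts = rng.poisson(sensor.point_density * area)
    if n_pts == 0 or surface.grid.size == 0:
        return np.empty((0, 3))

    x = rng.uniform(0, side, n_pts)
    y = rng.uniform(0, side, n_pts)
    h = surface.heights_at(x, y)
    canopy = h > 0.0

    z = np.zeros(n_pts)
    u_pen = rng.uniform(0, 1, n_pts)
    u_depth = rng.uniform(0, 1, n_pts)
    interior = canopy & (u_pen < sensor.penetration)
    surface_hit = canopy & ~interior
    z[interior] = u_depth[interior] * h[interior]
    z[surface_hit] = h[surface_hit]

    keep = np.ones(n_pts, dtype=bool)
    if sensor.tip_loss > 0:
        tip = surface_hit & (h >= 0.9 * surface.true_max_height)
        keep[tip & (rng.uniform(0, 1, n_pts) < sensor.tip_loss)] = False
    if sensor.drops_ground or not include_ground:
        keep &= canopy

    z = z + rng.normal(0.0, sensor.noise_sd, n_pts) if sensor.noise_sd > 0 else z
    keep &= (z >= sensor.min_detectable_z) & (z <= sensor.max_detectable_z)

    x, y, z = x[keep], y[keep], z[keep]
    xf, yf = x + origin[0], y + origin[1]
    if not sensor.normalized_output:
        z = z + (terrain(xf, yf) if callable(terrain) else terrain)
    return np.column_stack([xf, yf, z])


def simulate_fm(surface: TrueCanopy, fm_model: FMObservationModel, seed: int = 0) -> float:
    """Ruler measurement: mean of window-maxima plus observer error, >= 0."""
    side = surface.grid.shape[0] * surface.resolution
    if fm_model.window_side > side + 1e-12:
        raise InvalidParameterError("FM window larger than the plot")
    rng = spawn_rng(seed, "fm", surface.plot_id, surface.stage)
    n = surface.grid.shape[0]
    w = max(int(round(fm_model.window_side / surface.resolution)), 1)
    w = min(w, n)
    readings = []
    for _ in range(fm_model.k_locations):
        i = rng.integers(0, n - w + 1)
        j = rng.integers(0, n - w + 1)
        local_max = float(surface.grid[i : i + w, j : j + w].max())
        readings.append(local_max + rng.normal(0.0, fm_model.observer_sd))
    return max(float(np.mean(readings)), 0.0)


def simulate_lai(
    canopy: TrueCanopy, alpha: float = 5.0, lai_noise_sd: float = 0.3, seed: int = 0
) -> float:
    """Linear LAI proxy: ``alpha * cover_fraction * height + noise``, >= 0.

    Not a gap-fraction model — it only needs to be positively correlated with
    canopy size so that LAI-based stratification is meaningful.
    """
    if alpha <= 0:
        raise InvalidParameterError("alpha must be > 0")
    rng = spawn_rng(seed, "lai", canopy.plot_id, canopy.stage)
    value = alpha * canopy.realized_cover_fraction * canopy.true_max_height
    if lai_noise_sd > 0:
        value += rng.normal(0.0, lai_noise_sd)
    return max(float(value), 0.0)


# ---------------------------------------------------------------------------
# whole-field simulation
# ---------------------------------------------------------------------------


@dataclass
class FieldSimulation:
    """Everything one simulated trial produces.

    ``truth`` has one row per (plot, stage) with the true maximum height, the
    realized cover fraction, the FM reading and the LAI covariate; ``clouds``
    maps (sensor, stage) to an (n, 3) field-coordinate point cloud.
    """

    design: FieldDesign
    truth: pd.DataFrame
    clouds: dict[tuple[str, str], np.ndarray]
    sensors: dict[str, SensorModel]
    seed: int


def _alley_ground(
    design: FieldDesign,
    density: float,
    noise_sd: float,
    terrain,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ground returns over the inter-plot alleys (and any grid remainder)."""
    width, height = design.field_extent()
    area = width * height - design.n_plots * design.plot_side**2
    n = rng.poisson(density * max(area, 0.0))
    if n == 0:
        return np.empty((0, 3))
    # oversample the full extent, reject points inside plot footprints
    m = int(n * (width * height) / max(area, 1e-9) * 1.2) + 16
    x = rng.uniform(0, width, m)
    y = rng.uniform(0, height, m)
    pitch = design.pitch
    col = np.floor(x / pitch).astype(int)
    row = np.floor(y / pitch).astype(int)
    in_plot = (x - col * pitch < design.plot_side) & (y - row * pitch < design.plot_side)
    # grid cells past the final plot are open ground
    occupied = np.zeros((design.n_rows, design.n_cols), dtype=bool)
    occupied[design.plots["row"].to_numpy(), design.plots["col"].to_numpy()] = True
    valid = (row < design.n_rows) & (col < design.n_cols)
    in_plot &= valid
    in_plot[valid] &= occupied[row[valid], col[valid]]
    x, y = x[~in_plot][:n], y[~in_plot][:n]
    z = terrain(x, y) if callable(terrain) else np.full(len(x), float(terrain))
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, len(x))
    return np.column_stack([x, y, z])


def simulate_field(
    design: FieldDesign,
    stage_means: Mapping[str, float],
    sensors: Mapping[str, SensorModel] | None = None,
    fm_model: FMObservationModel | None = None,
    *,
    var_G: float = 0.010,
    var_E: float = 0.002,
    var_GE: float = 0.002,
    var_eps: float = 0.004,
    unevenness: float = 0.35,
    cover_fraction: float = 0.85,
    resolution: float = 0.01,
    lai_alpha: float = 5.0,
    lai_noise_sd: float = 0.3,
    terrain: float | Callable = 0.0,
    alley_ground_fraction: float = 0.25,
    seed: int = 0,
) -> FieldSimulation:
    """Run the complete forward model for every plot, stage and sensor.

    Each (plot, stage) gets one canopy surface shared by all sensors, the FM
    observer and the LAI covariate, so cross-source agreement reflects the
    sensing models rather than independent canopies.  Sensors that retain
    ground also see the alleys between plots (at ``alley_ground_fraction`` of
    their canopy density — partial occlusion), which is what the ground
    filter downstream feeds on.
    """
    sensors = dict(sensors) if sensors is not None else default_sensors()
    fm_model = fm_model or FMObservationModel()

    truth = simulate_true_heights(
        design, stage_means, var_G, var_E, var_GE, var_eps, seed=seed
    )

    clouds: dict[tuple[str, str], list[np.ndarray]] = {
        (s, stage): [] for s in sensors for stage in design.stages
    }
    fm_vals = np.empty(len(truth))
    lai_vals = np.empty(len(truth))
    cover_vals = np.empty(len(truth))

    plot_origin = {
        pid: (x0, y0)
        for pid, x0, y0 in zip(design.plots["plot_id"], design.plots["x0"], design.plots["y0"])
    }

    for idx, rec in enumerate(truth.itertuples(index=False)):
        surface = synthesize_surface(
            rec.true_max_height,
            unevenness=unevenness,
            cover_fraction=cover_fraction,
            resolution=resolution,
            seed=seed,
            plot_side=design.plot_side,
            plot_id=rec.plot_id,
            stage=rec.stage,
        )
        origin = plot_origin[rec.plot_id]
        for name, sensor in sensors.items():
            pts = sample_pointcloud(
                surface, sensor, include_ground=True, seed=seed, origin=origin, terrain=terrain
            )
            if len(pts):
                clouds[(name, rec.stage)].append(pts)
        fm_vals[idx] = simulate_fm(surface, fm_model, seed=seed)
        lai_vals[idx] = simulate_lai(surface, lai_alpha, lai_noise_sd, seed=seed)
        cover_vals[idx] = surface.realized_cover_fraction

    truth = truth.copy()
    truth["cover_fraction"] = cover_vals
    truth["fm_height"] = fm_vals
    truth["lai"] = lai_vals

    merged: dict[tuple[str, str], np.ndarray] = {}
    for stage_i, stage in enumerate(design.stages):
        for name, sensor in sensors.items():
            parts = clouds[(name, stage)]
            if not sensor.drops_ground and alley_ground_fraction > 0:
                rng = spawn_rng(seed, "alley", name, stage)
                parts.append(
                    _alley_ground(
                        design,
                        sensor.point_density * alley_ground_fraction,
                        sensor.noise_sd,
                        terrain,
                        rng,
                    )
                )
            merged[(name, stage)] = (
                np.vstack([p for p in parts if len(p)]) if parts else np.empty((0, 3))
            )

    return FieldSimulation(design=design, truth=truth, clouds=merged, sensors=sensors, seed=seed)
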