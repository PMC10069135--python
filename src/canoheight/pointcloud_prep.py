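"""Point-cloud preprocessing: clip, denoise, ground-filter, normalize, extract.

Takes a raw field point cloud (x, y, z in meters, co-registered across
sensors) to per-plot clouds of height above ground, mirroring the standard
clip → denoise → ground filter → normalize → plot extraction chain used in
plot-phenotyping surveys.  Ground filtering here is a reproducible simplified
scheme — per-cell minimum seeding with a tolerance band and neighbor
interpolation — in place of progressive-TIN densification with manual
revision, which is adequate for near-flat trial fields.

Clouds are plain ``(n, 3)`` float arrays throughout; provenance (sensor,
stage, plot) travels alongside in the light containers below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CanoheightError, ConfigError, FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GroundModel",
    "NormalizedPlotCloud",
    "read_pointcloud",
    "read_xyz",
    "write_xyz",
    "clip_to_extent",
    "denoise",
    "filter_ground",
    "normalize",
    "apply_min_height_filter",
    "extract_plots",
]


@dataclass
class GroundModel:
    """Gridded ground elevation over a cloud's extent.

    ``elevation`` is a (rows, cols) array; cells the filter could not seed are
    filled by iterative neighbor averaging before the model is returned, so
    every cell holds a value.
    """

    x0: float
    y0: float
    cell_size: float
    elevation: np.ndarray

    def elevation_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ground elevation at (x, y) via nearest-cell lookup.

        Points outside the gridded extent snap to the nearest border cell
        (extrapolation is logged by :func:`normalize`).
        """
        rows, cols = self.elevation.shape
        j = np.clip(((np.asarray(x) - self.x0) / self.cell_size).astype(int), 0, cols - 1)
        i = np.clip(((np.asarray(y) - self.y0) / self.cell_size).astype(int), 0, rows - 1)
        return self.elevation[i, j]


@dataclass
class NormalizedPlotCloud:
    """One plot's above-ground points; ``z`` is height above ground (m)."""

    plot_id: str
    points: np.ndarray
    sensor: str = ""
    stage: str = ""

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_xyz(path) -> np.ndarray:
    """Read an XYZ text cloud (whitespace-separated ``x y z`` per line).

    Malformed lines are rejected, counted and logged rather than raising.
    """
    pts = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                n_bad += 1
                continue
            try:
                pts.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError:
                n_bad += 1
    if n_bad:
        logger.warning("%s: rejected %d malformed line(s)", path, n_bad)
    return np.array(pts, dtype=float).reshape(-1, 3)


def write_xyz(points: np.ndarray, path) -> None:
    """Write an (n, 3) cloud as XYZ text with 6 decimal places (micrometer)."""
    np.savetxt(path, np.asarray(points, dtype=float).reshape(-1, 3), fmt="%.6f")


def read_pointcloud(path, format: str = "xyz") -> np.ndarray:
    """Load a point cloud; ``format`` is "xyz" or "las" (requires laspy)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"point-cloud file not found: {path}")
    if format == "xyz":
        return read_xyz(path)
    if format == "las":
        try:
            import laspy  # noqa: F401  (optional extra)
        except ImportError as exc:  # pragma: no cover - laspy not installed here
            raise FormatError("LAS support requires the optional 'laspy' dependency") from exc
        las = laspy.read(str(path))  # pragma: no cover
        return np.column_stack([las.x, las.y, las.z])  # pragma: no cover
    raise FormatError(f"unknown point-cloud format: {format!r}")


# ---------------------------------------------------------------------------
# cloud operations
# ---------------------------------------------------------------------------


def clip_to_extent(points: np.ndarray, box: tuple[float, float, float, float]) -> np.ndarray:
    """Keep points with ``x0 <= x < x1`` and ``y0 <= y < y1`` (half-open)."""
    x0, y0, x1, y1 = box
    if not (x0 < x1 and y0 < y1):
        raise InvalidParameterError(f"invalid box {box}: need x0 < x1 and y0 < y1")
    pts = np.asarray(points).reshape(-1, 3)
    m = (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    return pts[m]


def denoise(points: np.ndarray, k_neighbors: int = 10, sd_multiplier: float = 3.0) -> np.ndarray:
    """Statistical outlier removal.

    A point is dropped when its mean distance to its ``k_neighbors`` nearest
    neighbors exceeds the global mean of that quantity by more than
    ``sd_multiplier`` standard deviations.  Deterministic; replaces the
    manual cleanup step of interactive tools.
    """
    if k_neighbors < 1:
        raise InvalidParameterError("k_neighbors must be >= 1")
    pts = np.asarray(points).reshape(-1, 3)
    if len(pts) <= k_neighbors:
        logger.warning("denoise: cloud of %d points <= k=%d, returned unchanged", len(pts), k_neighbors)
        return pts
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_neighbors + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    mu, sd = mean_d.mean(), mean_d.std()
    keep = mean_d <= mu + sd_multiplier * sd
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("denoise: removed %d of %d points", n_removed, len(pts))
    return pts[keep]


def _fill_empty_cells(elev: np.ndarray, has_data: np.ndarray) -> np.ndarray:
    """Iteratively fill unseeded cells with the mean of seeded neighbors."""
    elev = elev.copy()
    filled = has_data.copy()
    n_empty = int((~filled).sum())
    if n_empty:
        logger.info("ground model: interpolating %d empty cell(s) from neighbors", n_empty)
    while not filled.all():
        padded = np.pad(elev, 1, constant_values=np.nan)
        padded[np.pad(~filled, 1, constant_values=True)] = np.nan
        neigh = np.stack(
            [
                padded[:-2, 1:-1],
                padded[2:, 1:-1],
                padded[1:-1, :-2],
                padded[1:-1, 2:],
                padded[:-2, :-2],
                padded[:-2, 2:],
                padded[2:, :-2],
                padded[2:, 2:],
            ]
        )
        with np.errstate(invalid="ignore"):
            mean_neigh = np.nanmean(neigh, axis=0)
        grow = ~filled & ~np.isnan(mean_neigh)
        if not grow.any():  # isolated region with no seeds anywhere: flat fallback
            elev[~filled] = np.nanmean(elev[filled]) if filled.any() else 0.0
            break
        elev[grow] = mean_neigh[grow]
        filled |= grow
    return elev


def filter_ground(
    points: np.ndarray, cell_size: float = 0.5, z_tolerance: float = 0.05
) -> tuple[np.ndarray, GroundModel]:
    """Label ground points and build a gridded ground model.

    The minimum z of each ``cell_size`` cell seeds the ground surface; points
    within ``z_tolerance`` of their cell's seed are labeled ground.  Cells
    without points are filled by neighbor interpolation.  Returns the boolean
    ground mask and the :class:`GroundModel`.
    """
    if cell_size <= 0:
        raise InvalidParameterError("cell_size must be > 0")
    pts = np.asarray(points).reshape(-1, 3)
    if len(pts) == 0:
        raise CanoheightError("filter_ground: empty cloud")

    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    cols = int((pts[:, 0].max() - x0) / cell_size) + 1
    rows = int((pts[:, 1].max() - y0) / cell_size) + 1
    j = np.clip(((pts[:, 0] - x0) / cell_size).astype(int), 0, cols - 1)
    i = np.clip(((pts[:, 1] - y0) / cell_size).astype(int), 0, rows - 1)

    elev = np.full((rows, cols), np.inf)
    np.minimum.at(elev, (i, j), pts[:, 2])
    has_data = np.isfinite(elev)
    elev[~has_data] = np.nan
    elev = _fill_empty_cells(elev, has_data)

    ground_mask = pts[:, 2] <= elev[i, j] + z_tolerance
    model = GroundModel(x0=float(x0), y0=float(y0), cell_size=float(cell_size), elevation=elev)
    return ground_mask, model


def normalize(points: np.ndarray, ground: GroundModel) -> np.ndarray:
    """Convert absolute z to height above ground (``z - ground elevation``).

    The sign convention makes canopy heights positive.  Small negative values
    (points marginally below the interpolated ground) are clamped to 0.
    Points outside the ground model's extent use the nearest border cell and
    are logged.
    """
    pts = np.asarray(points).reshape(-1, 3)
    if len(pts) == 0:
        return pts.copy()
    rows, cols = ground.elevation.shape
    x_max = ground.x0 + cols * ground.cell_size
    y_max = ground.y0 + rows * ground.cell_size
    outside = (
        (pts[:, 0] < ground.x0)
        | (pts[:, 0] >= x_max + ground.cell_size)
        | (pts[:, 1] < ground.y0)
        | (pts[:, 1] >= y_max + ground.cell_size)
    )
    if outside.any():
        logger.warning("normalize: %d point(s) outside ground extent, extrapolated", int(outside.sum()))
    z = pts[:, 2] - ground.elevation_at(pts[:, 0], pts[:, 1])
    return np.column_stack([pts[:, 0], pts[:, 1], np.maximum(z, 0.0)])


def apply_min_height_filter(points: np.ndarray, z_min: float) -> np.ndarray:
    """Keep normalized points with ``z >= z_min`` (inclusive).

    With ``z_min=0.28`` this documents the gantry scanner's acquisition-time
    ground filter for clouds that arrive already truncated.
    """
    if z_min < 0:
        raise InvalidParameterError("z_min must be >= 0")
    pts = np.asarray(points).reshape(-1, 3)
    return pts[pts[:, 2] >= z_min]


def extract_plots(
    points: np.ndarray,
    plot_map: pd.DataFrame,
    sensor: str = "",
    stage: str = "",
) -> dict[str, NormalizedPlotCloud]:
    """Split a normalized field cloud into per-plot clouds.

    ``plot_map`` needs columns ``plot_id, x0, y0, x1, y1`` with half-open,
    non-overlapping boxes.  Every plot appears in the result; plots with zero
    points are reported in the log, never silently dropped.
    """
    required = {"plot_id", "x0", "y0", "x1", "y1"}
    if not required.issubset(plot_map.columns):
        raise ConfigError([f"plot map missing columns: {sorted(required - set(plot_map.columns))}"])
    boxes = plot_map[["x0", "y0", "x1", "y1"]].to_numpy(dtype=float)
    x0, y0, x1, y1 = boxes.T
    overlap = (
        (x0[:, None] < x1[None, :])
        & (x0[None, :] < x1[:, None])
        & (y0[:, None] < y1[None, :])
        & (y0[None, :] < y1[:, None])
    )
    np.fill_diagonal(overlap, False)
    if overlap.any():
        a, b = np.argwhere(overlap)[0]
        raise ConfigError(
            [
                "overlapping plot boxes: "
                f"{plot_map['plot_id'].iloc[a]} and {plot_map['plot_id'].iloc[b]}"
            ]
        )

    pts = np.asarray(points).reshape(-1, 3)
    order = np.argsort(pts[:, 0], kind="stable") if len(pts) else np.empty(0, dtype=int)
    xs = pts[order, 0]
    out: dict[str, NormalizedPlotCloud] = {}
    empty: list[str] = []
    for rec in plot_map.itertuples(index=False):
        lo = np.searchsorted(xs, rec.x0, side="left")
        hi = np.searchsorted(xs, rec.x1, side="left")
        cand = pts[order[lo:hi]]
        sub = cand[(cand[:, 1] >= rec.y0) & (cand[:, 1] < rec.y1)]
        out[rec.plot_id] = NormalizedPlotCloud(rec.plot_id, sub, sensor=sensor, stage=stage)
        if len(sub) == 0:
            empty.append(rec.plot_id)
    if empty:
        logger.warning("extract_plots: %d plot(s) with zero points: %s", len(empty), empty[:10])
    return out
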