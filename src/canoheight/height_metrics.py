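"""Plot-level canopy-height metrics and optimal-quantile selection.

A plot's canopy height is summarized either as Hmax (the maximum normalized
point height) or as a height quantile Hq for q in 80..99 % — upper quantiles
are robust to stray high returns, which is why plot-phenotyping pipelines
compare the whole H80..H99 ladder against ruler measurements and keep the
best-agreeing one per sensor.

Quantiles use the linear-interpolation estimator (the plotting-position rule
under which the p-quantile of 0..100 over 101 points returns p); the choice
is exposed through the ``method`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy_compare import pearson_r, rmse
from .errors import InsufficientDataError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "HeightMetricSpec",
    "QUANTILE_RANGE",
    "METRIC_NAMES",
    "compute_height_metric",
    "compute_all_metrics",
    "metrics_long_table",
    "select_optimal_metric",
]

QUANTILE_RANGE = tuple(range(80, 100))
METRIC_NAMES: tuple[str, ...] = tuple(f"H{q}" for q in QUANTILE_RANGE) + ("Hmax",)


@dataclass(frozen=True)
class HeightMetricSpec:
    """Either ``kind="Hmax"`` or ``kind="Hq"`` with ``q`` in 80..99."""

    kind: str
    q: int | None = None

    def __post_init__(self):
        if self.kind == "Hmax":
            if self.q is not None:
                raise InvalidParameterError("Hmax takes no quantile")
        elif self.kind == "Hq":
            if self.q is None or not 80 <= int(self.q) <= 99:
                raise InvalidParameterError(f"quantile must be an integer in [80, 99], got {self.q}")
        else:
            raise InvalidParameterError(f"unknown metric kind {self.kind!r}")

    @property
    def name(self) -> str:
        return "Hmax" if self.kind == "Hmax" else f"H{self.q}"

    @classmethod
    def from_name(cls, name: str) -> "HeightMetricSpec":
        if name == "Hmax":
            return cls("Hmax")
        if name.startswith("H"):
            return cls("Hq", int(name[1:]))
        raise InvalidParameterError(f"unknown metric name {name!r}")


def compute_height_metric(z: np.ndarray, spec: HeightMetricSpec, method: str = "linear") -> float:
    """One metric of a plot's normalized heights; NaN for an empty cloud."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        logger.warning("compute_height_metric: empty cloud -> missing value")
        return float("nan")
    if spec.kind == "Hmax":
        return float(z.max())
    return float(np.percentile(z, spec.q, method=method))


def compute_all_metrics(z: np.ndarray, method: str = "linear") -> pd.Series:
    """All 21 metrics (H80..H99, Hmax) of one plot cloud, as a named Series."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        logger.warning("compute_all_metrics: empty cloud -> missing values")
        return pd.Series(np.nan, index=list(METRIC_NAMES))
    vals = np.percentile(z, QUANTILE_RANGE, method=method)
    return pd.Series(
        np.append(vals, z.max()), index=list(METRIC_NAMES), dtype=float
    )


def metrics_long_table(plot_clouds, sensor: str, stage: str, method: str = "linear") -> pd.DataFrame:
    """Metrics for a set of per-plot clouds, tidy long format.

    ``plot_clouds`` maps plot_id to a :class:`NormalizedPlotCloud` (or any
    object with a ``z`` array).  Empty clouds propagate as NaN.
    """
    rows = []
    for plot_id, cloud in plot_clouds.items():
        mets = compute_all_metrics(cloud.z, method=method)
        for name, value in mets.items():
            rows.append((plot_id, stage, sensor, name, value))
    return pd.DataFrame(rows, columns=["plot_id", "stage", "source", "metric", "height_m"])


def select_optimal_metric(
    height_table: pd.DataFrame,
    source: str,
    fm_column: str = "fm_height",
) -> tuple[HeightMetricSpec, pd.DataFrame]:
    """Choose the metric agreeing best with the ruler reference.

    ``height_table`` is long format (``plot_id, stage, source, metric,
    height_m``) with an ``fm_height`` column already joined per row.  The
    winner maximizes Pearson r with FM; ties break by lowest RMSE, then by
    lower quantile (Hmax last).  The full per-metric score table is returned
    for audit.
    """
    sub = height_table[height_table["source"] == source].dropna(subset=["height_m", fm_column])
    if sub.empty or sub["plot_id"].nunique() < 3:
        raise InsufficientDataError(
            f"select_optimal_metric({source}): need >= 3 paired plots"
        )
    scores = []
    for name in METRIC_NAMES:
        block = sub[sub["metric"] == name]
        if len(block) < 3:
            continue
        y = block[fm_column].to_numpy()
        y_hat = block["height_m"].to_numpy()
        scores.append(
            {
                "metric": name,
                "r": pearson_r(y, y_hat),
                "rmse": rmse(y, y_hat),
                "n": len(block),
            }
        )
    if not scores:
        raise InsufficientDataError(f"select_optimal_metric({source}): no metric has >= 3 pairs")
    table = pd.DataFrame(scores)

    def sort_rank(name: str) -> int:  # lower quantile wins ties; Hmax ranked last
        return 100 if name == "Hmax" else int(name[1:])

    table["_rank"] = table["metric"].map(sort_rank)
    # rank on rounded statistics so ties-by-construction are not split by
    # floating-point summation noise
    table["_r"] = table["r"].round(12)
    table["_rmse"] = table["rmse"].round(12)
    best = table.sort_values(
        by=["_r", "_rmse", "_rank"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    table = table.drop(columns=["_rank", "_r", "_rmse"])
    return HeightMetricSpec.from_name(best["metric"]), table
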