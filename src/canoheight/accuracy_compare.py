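"""Paired agreement statistics and stratified comparison tables.

Five statistics summarize agreement between a predicted height series and a
reference series: Pearson's r, RMSE, relative RMSE (% of the reference mean),
Bias (mean of prediction minus reference, so underestimation is negative) and
relative Bias.  Comparisons run overall and stratified by field-measured
canopy-height (CH) bins, LAI bins and growth stage, with the gantry scanner
(GLS) restricted to plots whose measured height is below its 0.82 m ceiling.

A secondary ``r_fit`` column carries the square-root-of-R-squared form of the
correlation (identical to |r| for an ordinary least-squares fit); it is
reported alongside because both conventions circulate in the agreement
literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "AccuracyReport",
    "GroupingScheme",
    "SENSOR_SOURCES",
    "FM_PAIRINGS",
    "CROSS_PAIRINGS",
    "default_grouping_schemes",
    "pearson_r",
    "eq_fit_r",
    "rmse",
    "rmse_pct",
    "bias",
    "bias_pct",
    "evaluate_pair",
    "assign_groups",
    "gls_eligibility",
    "comparison_matrix",
]

SENSOR_SOURCES: tuple[str, ...] = ("TLS", "BLS", "GLS", "DAP")
FM_PAIRINGS: tuple[tuple[str, str], ...] = tuple((s, "FM") for s in SENSOR_SOURCES)
CROSS_PAIRINGS: tuple[tuple[str, str], ...] = (
    ("TLS", "BLS"),
    ("BLS", "DAP"),
    ("DAP", "TLS"),
    ("TLS", "GLS"),
    ("BLS", "GLS"),
    ("DAP", "GLS"),
)


@dataclass(frozen=True)
class AccuracyReport:
    """The five agreement statistics of one paired comparison."""

    r: float
    rmse: float
    rmse_pct: float
    bias: float
    bias_pct: float
    n: int
    r_fit: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "rmse": self.rmse,
            "rmse_pct": self.rmse_pct,
            "bias": self.bias,
            "bias_pct": self.bias_pct,
            "n": self.n,
            "r_fit": self.r_fit,
        }


@dataclass(frozen=True)
class GroupingScheme:
    """Stratification of plot observations.

    For ``variable`` "CH" or "LAI", ``edges`` are ordered bin boundaries and
    ``names`` label the ``len(edges) - 1`` bins; bins are half-open
    ``[lo, hi)`` except the last, which is closed.  For "GS" the groups are
    the growth-stage labels themselves.
    """

    variable: str
    names: tuple[str, ...]
    edges: tuple[float, ...] = ()

    def __post_init__(self):
        if self.variable not in {"CH", "LAI", "GS"}:
            raise ConfigError([f"unknown grouping variable {self.variable!r}"])
        if self.variable != "GS":
            if len(self.edges) != len(self.names) + 1:
                raise ConfigError([f"{self.variable}: need len(edges) == len(names) + 1"])
            if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
                raise ConfigError([f"{self.variable}: edges must be strictly increasing"])


def default_grouping_schemes(stages: Sequence[str]) -> dict[str, GroupingScheme]:
    """The trial's standard CH / LAI / GS stratifications."""
    return {
        "CH": GroupingScheme("CH", ("CH1", "CH2", "CH3", "CH4"), (0.3, 0.6, 0.8, 1.0, 1.4)),
        "LAI": GroupingScheme("LAI", ("LAI1", "LAI2", "LAI3", "LAI4"), (0.0, 2.0, 4.0, 6.0, 8.0)),
        "GS": GroupingScheme("GS", tuple(stages)),
    }


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def _paired(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise InvalidParameterError("paired vectors must have equal length")
    ok = np.isfinite(y) & np.isfinite(y_hat)
    return y[ok], y_hat[ok]


def pearson_r(y, y_hat) -> float:
    """Product-moment correlation; NaN when n < 2 or either variance is 0."""
    y, y_hat = _paired(y, y_hat)
    if len(y) < 2 or np.std(y) == 0 or np.std(y_hat) == 0:
        return float("nan")
    return float(np.corrcoef(y, y_hat)[0, 1])


def eq_fit_r(y, y_hat) -> float:
    """sqrt(1 - SSE/SST) against the OLS fit of y on y_hat (= |pearson r|)."""
    r = pearson_r(y, y_hat)
    return float("nan") if math.isnan(r) else abs(r)


def rmse(y, y_hat) -> float:
    y, y_hat = _paired(y, y_hat)
    if len(y) == 0:
        return float("nan")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rmse_pct(y, y_hat) -> float:
    """RMSE as a percentage of the reference mean; NaN when that mean is 0."""
    y, y_hat = _paired(y, y_hat)
    if len(y) == 0 or np.mean(y) == 0:
        return float("nan")
    return 100.0 * rmse(y, y_hat) / float(np.mean(y))


def bias(y, y_hat) -> float:
    """Mean(prediction - reference): negative means underestimation."""
    y, y_hat = _paired(y, y_hat)
    if len(y) == 0:
        return float("nan")
    return float(np.mean(y_hat - y))


def bias_pct(y, y_hat) -> float:
    y, y_hat = _paired(y, y_hat)
    if len(y) == 0 or np.mean(y) == 0:
        return float("nan")
    return 100.0 * bias(y, y_hat) / float(np.mean(y))


def evaluate_pair(y, y_hat) -> AccuracyReport:
    """All five statistics (plus the fitted-line r form) in one record."""
    y, y_hat = _paired(y, y_hat)
    return AccuracyReport(
        r=pearson_r(y, y_hat),
        rmse=rmse(y, y_hat),
        rmse_pct=rmse_pct(y, y_hat),
        bias=bias(y, y_hat),
        bias_pct=bias_pct(y, y_hat),
        n=len(y),
        r_fit=eq_fit_r(y, y_hat),
    )


# ---------------------------------------------------------------------------
# grouping and eligibility
# ---------------------------------------------------------------------------

OUT_OF_RANGE = "out_of_range"


def assign_groups(values, scheme: GroupingScheme) -> np.ndarray:
    """Assign each observation to exactly one group (or ``out_of_range``).

    For CH/LAI the grouping value is the *field-measured* quantity; bins are
    half-open except the last, which includes its upper edge.  For GS the
    values are stage labels and must match the scheme's names.
    """
    if scheme.variable == "GS":
        vals = np.asarray(values, dtype=object)
        known = set(scheme.names)
        return np.array([v if v in known else OUT_OF_RANGE for v in vals], dtype=object)
    vals = np.asarray(values, dtype=float)
    edges = np.asarray(scheme.edges)
    idx = np.searchsorted(edges, vals, side="right") - 1
    labels = np.full(vals.shape, OUT_OF_RANGE, dtype=object)
    in_bin = (idx >= 0) & (idx < len(scheme.names))
    labels[in_bin] = np.asarray(scheme.names, dtype=object)[idx[in_bin]]
    labels[vals == edges[-1]] = scheme.names[-1]  # last bin closed
    labels[~np.isfinite(vals)] = OUT_OF_RANGE
    return labels


def gls_eligibility(fm_heights, ceiling: float = 0.82) -> np.ndarray:
    """True where the measured height is strictly below the GLS ceiling."""
    return np.asarray(fm_heights, dtype=float) < ceiling


# ---------------------------------------------------------------------------
# the full comparison matrix
# ---------------------------------------------------------------------------


def comparison_matrix(
    table: pd.DataFrame,
    schemes: Mapping[str, GroupingScheme] | None = None,
    gls_ceiling: float = 0.82,
    pairings: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Every pairwise comparison, pooled and per subgroup, as a tidy frame.

    ``table`` is wide: one row per plot observation with columns ``FM`` and
    the sensor sources present, plus ``lai`` and ``stage`` when LAI/GS
    schemes are requested.  In a pairing (a, b), b is the reference.  Rows
    with a "Mean" group average the subgroup statistics unweighted, matching
    the convention of trial summary tables with unequal group sizes.  Any
    comparison involving GLS keeps only GLS-eligible observations.
    """
    sources = [s for s in SENSOR_SOURCES if s in table.columns]
    if len(sources) + ("FM" in table.columns) < 2:
        raise ConfigError(["comparison_matrix: need at least two sources in the table"])
    if pairings is None:
        pairings = [(a, b) for a, b in FM_PAIRINGS if a in sources and b in table.columns]
        pairings += [(a, b) for a, b in CROSS_PAIRINGS if a in sources and b in sources]
    schemes = schemes or {}

    eligible = (
        gls_eligibility(table["FM"].to_numpy(), gls_ceiling)
        if "FM" in table.columns
        else np.ones(len(table), dtype=bool)
    )

    group_columns: dict[str, np.ndarray] = {}
    for var, scheme in schemes.items():
        if scheme.variable == "CH":
            group_columns[var] = assign_groups(table["FM"].to_numpy(), scheme)
        elif scheme.variable == "LAI":
            group_columns[var] = assign_groups(table["lai"].to_numpy(), scheme)
        else:
            group_columns[var] = assign_groups(table["stage"].to_numpy(), scheme)

    stat_cols = ["r", "rmse", "rmse_pct", "bias", "bias_pct"]
    rows = []

    def emit(pred, ref, mask, group_var, group):
        sub = table.loc[mask]
        rep = evaluate_pair(sub[ref].to_numpy(), sub[pred].to_numpy())
        rows.append({"pairing": f"{pred} vs {ref}", "group_var": group_var, "group": group, **rep.as_dict()})

    for pred, ref in pairings:
        needs_gls = "GLS" in (pred, ref)
        base = eligible if needs_gls else np.ones(len(table), dtype=bool)
        base = base & table[pred].notna().to_numpy() & table[ref].notna().to_numpy()
        emit(pred, ref, base, "pooled", "all")
        for var, scheme in schemes.items():
            labels = group_columns[var]
            sub_stats = []
            for gname in scheme.names:
                mask = base & (labels == gname)
                emit(pred, ref, mask, var, gname)
                if rows[-1]["n"] >= 2:
                    sub_stats.append({c: rows[-1][c] for c in stat_cols})
            mean_row = {
                "pairing": f"{pred} vs {ref}",
                "group_var": var,
                "group": "Mean",
                "n": int(sum(1 for _ in sub_stats)),
                "r_fit": float("nan"),
            }
            for c in stat_cols:
                vals = [s[c] for s in sub_stats if np.isfinite(s[c])]
                mean_row[c] = float(np.mean(vals)) if vals else float("nan")
            rows.append(mean_row)

    return pd.DataFrame(rows)


def pivot_comparison(matrix: pd.DataFrame, group_var: str) -> pd.DataFrame:
    """Reshape the tidy matrix into a groups x pairings summary table."""
    sub = matrix[matrix["group_var"].isin([group_var, "pooled"])]
    return sub.pivot_table(
        index="group", columns="pairing", values=["r", "rmse", "bias"], sort=False
    )
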