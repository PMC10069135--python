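"""Set-intersection attribution of height disagreements to FM or a sensor.

For each plot the relative residual of a sensor against the ruler reference
is ``delta = |H_sensor - H_FM| / H_FM``.  Plots with delta >= tau (default
20 %) form that sensor's *suspicious set* S_a.  A plot suspicious to ALL four
sensors implicates the reference itself (Error_FM = intersection of the four
sets); a plot suspicious to a sensor but not in Error_FM is attributed to
that sensor (Error_a = S_a minus Error_FM).

Signed residuals are kept alongside the absolute ones so the *direction* of
disagreement (e.g. systematic underestimation by a range-limited scanner)
remains diagnosable, but only |delta| drives set membership.  A relaxed
variant flags the reference when at least m of the four sensors are
suspicious; with m = 4 it coincides with the strict rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy_compare import SENSOR_SOURCES, gls_eligibility
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionResult",
    "relative_residual",
    "residual_table",
    "suspicious_set",
    "attribute_errors",
    "attribution_report",
]


@dataclass
class AttributionResult:
    """Suspicious sets and their attribution for one plot universe."""

    suspicious: dict[str, set]  # S_a per sensor
    error_fm: set
    error_by_source: dict[str, set]
    tau: float
    universe: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        out = {"FM": len(self.error_fm)}
        out.update({a: len(s) for a, s in self.error_by_source.items()})
        return out


def relative_residual(h_sensor: float, h_fm: float) -> float:
    """``|h_sensor - h_fm| / h_fm``; undefined (NaN) for h_fm <= 0."""
    if h_fm <= 0 or not np.isfinite(h_fm) or not np.isfinite(h_sensor):
        return float("nan")
    return abs(h_sensor - h_fm) / h_fm


def residual_table(table: pd.DataFrame, sources=SENSOR_SOURCES) -> pd.DataFrame:
    """Per-plot signed and absolute relative residuals for each sensor.

    ``table`` is wide with an ``FM`` column and one column per sensor; the
    index (or a ``plot_id`` column) identifies the observation.  Rows with
    FM <= 0 are excluded with a log entry.
    """
    df = table.copy()
    if "plot_id" in df.columns:
        key = df["plot_id"].astype(str)
        if "stage" in df.columns:
            key = key + "@" + df["stage"].astype(str)
        df = df.set_index(key)
    bad = ~(df["FM"] > 0)
    if bad.any():
        logger.warning("residual_table: %d plot(s) with FM <= 0 excluded", int(bad.sum()))
        df = df[~bad]
    rows = []
    for pid, rec in df.iterrows():
        for a in sources:
            if a not in df.columns:
                continue
            signed = (rec[a] - rec["FM"]) / rec["FM"]
            rows.append(
                {
                    "plot_id": pid,
                    "source": a,
                    "delta_signed": signed,
                    "delta_abs": abs(signed),
                }
            )
    return pd.DataFrame(rows)


def suspicious_set(residuals: pd.DataFrame, source: str, tau: float = 0.2) -> set:
    """S_a: plots whose absolute relative residual is >= tau (inclusive)."""
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    sub = residuals[(residuals["source"] == source) & residuals["delta_abs"].notna()]
    return set(sub.loc[sub["delta_abs"] >= tau, "plot_id"])


def attribute_errors(
    s_tls: set, s_bls: set, s_gls: set, s_dap: set, tau: float = 0.2, universe: set | None = None
) -> AttributionResult:
    """Strict set algebra: Error_FM is the 4-way intersection.

    Error_a = S_a minus Error_FM for each sensor, so the attributions are
    pairwise disjoint from Error_FM by construction.
    """
    suspicious = {"TLS": set(s_tls), "BLS": set(s_bls), "GLS": set(s_gls), "DAP": set(s_dap)}
    error_fm = set.intersection(*suspicious.values())
    error_by_source = {a: s - error_fm for a, s in suspicious.items()}
    return AttributionResult(
        suspicious=suspicious,
        error_fm=error_fm,
        error_by_source=error_by_source,
        tau=tau,
        universe=set(universe) if universe is not None else set().union(*suspicious.values()),
    )


def attribution_report(
    table: pd.DataFrame,
    tau: float = 0.2,
    relaxed_m: int | None = 3,
    gls_ceiling: float = 0.82,
    restrict_gls: bool = True,
) -> tuple[AttributionResult, AttributionResult | None, pd.DataFrame]:
    """Full attribution on a wide height table.

    The plot universe keeps only observations where all four sensor heights
    and a positive FM are present, and (by default) the measured height is
    below the GLS ceiling — all four comparisons must exist for the
    intersection rule to be meaningful; exclusions are logged.

    Returns ``(strict, relaxed, residuals)``; ``relaxed`` flags the reference
    when >= ``relaxed_m`` of the 4 sensors are suspicious (None disables it).
    The residual frame carries signed/absolute deltas and a suspicious flag.
    """
    df = table.copy()
    n0 = len(df)
    keep = df["FM"].notna() & (df["FM"] > 0)
    for a in SENSOR_SOURCES:
        keep &= df[a].notna()
    if restrict_gls:
        keep &= gls_eligibility(df["FM"].to_numpy(), gls_ceiling)
    df = df[keep]
    if len(df) < n0:
        logger.info(
            "attribution_report: %d of %d observation(s) excluded (missing source, "
            "nonpositive FM, or above the GLS ceiling)",
            n0 - len(df),
            n0,
        )

    residuals = residual_table(df)
    residuals["suspicious"] = residuals["delta_abs"] >= tau
    sets = {a: suspicious_set(residuals, a, tau) for a in SENSOR_SOURCES}
    universe = set(residuals["plot_id"])
    strict = attribute_errors(sets["TLS"], sets["BLS"], sets["GLS"], sets["DAP"], tau, universe)

    relaxed = None
    if relaxed_m is not None:
        if not 1 <= relaxed_m <= 4:
            raise InvalidParameterError("relaxed_m must be in 1..4")
        counts: dict = {}
        for a in SENSOR_SOURCES:
            for pid in sets[a]:
                counts[pid] = counts.get(pid, 0) + 1
        relaxed_fm = {pid for pid, c in counts.items() if c >= relaxed_m}
        relaxed = AttributionResult(
            suspicious=sets,
            error_fm=relaxed_fm,
            error_by_source={a: sets[a] - relaxed_fm for a in SENSOR_SOURCES},
            tau=tau,
            universe=universe,
        )
    return strict, relaxed, residuals
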