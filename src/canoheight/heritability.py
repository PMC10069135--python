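"""Variance components and broad-sense heritability for a G x E x rep trial.

The design crosses g genotypes with e nitrogen treatments and r replicates.
Effects come from marginal means of the balanced table (method of moments):

    G_i  = genotype mean - grand mean
    E_j  = treatment mean - grand mean
    GE_ij = cell mean - genotype mean - treatment mean + grand mean

and the printed closed forms sum squared effects:

    sigma2_G  = sum_i G_i^2 / (g - 1)
    sigma2_E  = sum_j E_j^2 / (e - 1)
    sigma2_GE = sum_ij GE_ij^2 / ((g - 1)(e - 1))

with the residual variance taken as the within-cell replicate mean square,
sigma2_eps = sum resid^2 / (g e (r - 1)).  Broad-sense heritability on a
genotype-mean basis is

    H2 = sigma2_G / (sigma2_G + sigma2_GE / e + sigma2_eps / (r e)).

Note the effect-sum forms make sigma2_G the genotype-mean variance, which is
upwardly biased by within-genotype noise relative to an expected-mean-square
decomposition; ``ems_correction=True`` switches on the EMS-corrected
estimates for users who want the classical ANOVA components instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy_compare import GroupingScheme, assign_groups, gls_eligibility
from .errors import ConfigError, IncompleteDesignError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "TwoWayEffects",
    "VarianceComponents",
    "HeritabilityResult",
    "estimate_effects",
    "variance_components",
    "broad_sense_h2",
    "h2_for_cells",
    "h2_by_group",
]


@dataclass
class TwoWayEffects:
    """Marginal-mean decomposition of a balanced genotype x treatment table."""

    grand_mean: float
    G: pd.Series  # indexed by genotype
    E: pd.Series  # indexed by treatment
    GE: pd.DataFrame  # genotype x treatment
    residuals: np.ndarray
    g: int
    e: int
    r_reps: int


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_E: float
    sigma2_GE: float
    sigma2_eps: float
    truncated: bool = False  # any negative estimate clamped to zero


@dataclass
class HeritabilityResult:
    H2: float
    components: VarianceComponents | None
    g: int
    e: int
    r_reps: int
    n_varieties_used: int
    group: str = "all"

    @property
    def defined(self) -> bool:
        return self.components is not None and math.isfinite(self.H2)


def estimate_effects(cells: pd.DataFrame, value_col: str = "value") -> TwoWayEffects:
    """Decompose a balanced ``genotype, treatment, replicate, value`` table.

    Raises :class:`IncompleteDesignError` listing offending cells when the
    table is unbalanced or has missing values.
    """
    required = {"genotype", "treatment", "replicate", value_col}
    if not required.issubset(cells.columns):
        raise IncompleteDesignError(f"cells table missing columns: {sorted(required - set(cells.columns))}")
    df = cells[["genotype", "treatment", "replicate", value_col]].rename(columns={value_col: "value"})
    if df["value"].isna().any():
        bad = df[df["value"].isna()][["genotype", "treatment", "replicate"]]
        raise IncompleteDesignError("missing phenotype values", bad.itertuples(index=False))

    counts = df.groupby(["genotype", "treatment"], sort=True)["value"].count()
    genotypes = counts.index.get_level_values(0).unique()
    treatments = counts.index.get_level_values(1).unique()
    r_set = set(counts)
    if len(r_set) != 1 or len(counts) != len(genotypes) * len(treatments):
        offending = counts[counts != counts.max()].index.tolist()
        raise IncompleteDesignError(
            f"unbalanced design: cell replicate counts {sorted(r_set)}", offending
        )
    r_reps = r_set.pop()
    g, e = len(genotypes), len(treatments)

    grand = df["value"].mean()
    G = df.groupby("genotype", sort=True)["value"].mean() - grand
    E = df.groupby("treatment", sort=True)["value"].mean() - grand
    cell_means = df.groupby(["genotype", "treatment"], sort=True)["value"].mean().unstack()
    GE = cell_means.sub(G + grand, axis=0).sub(E, axis=1)
    resid = (
        df["value"].to_numpy()
        - cell_means.stack().reindex(
            pd.MultiIndex.from_arrays([df["genotype"], df["treatment"]])
        ).to_numpy()
    )
    return TwoWayEffects(
        grand_mean=float(grand), G=G, E=E, GE=GE, residuals=resid, g=g, e=e, r_reps=int(r_reps)
    )


def variance_components(
    effects: TwoWayEffects, ems_correction: bool = False
) -> VarianceComponents:
    """Closed-form component estimates from the effect sums of squares.

    ``sigma2_eps`` is NaN when there is a single replicate (no within-cell
    information).  With ``ems_correction`` the genotype and interaction
    components are the classical expected-mean-square versions
    (MS differences divided by the replication factors), clamped at zero.
    """
    g, e, r = effects.g, effects.e, effects.r_reps
    sum_G2 = float((effects.G**2).sum())
    sum_E2 = float((effects.E**2).sum())
    sum_GE2 = float((effects.GE**2).to_numpy().sum())
    s2_G = sum_G2 / (g - 1) if g >= 2 else float("nan")
    s2_E = sum_E2 / (e - 1) if e >= 2 else float("nan")
    s2_GE = sum_GE2 / ((g - 1) * (e - 1)) if g >= 2 and e >= 2 else float("nan")
    if r >= 2:
        s2_eps = float((effects.residuals**2).sum()) / (g * e * (r - 1))
    else:
        s2_eps = float("nan")

    truncated = False
    if ems_correction:
        # MS_GE = r * sum_GE2/((g-1)(e-1)); sigma2_GE = (MS_GE - MS_eps)/r, etc.
        ms_eps = s2_eps
        ms_ge = r * s2_GE if math.isfinite(s2_GE) else float("nan")
        ms_g = e * r * s2_G if math.isfinite(s2_G) else float("nan")
        s2_GE_c = (ms_ge - ms_eps) / r if math.isfinite(ms_ge) and math.isfinite(ms_eps) else float("nan")
        s2_G_c = (ms_g - ms_ge) / (e * r) if math.isfinite(ms_g) and math.isfinite(ms_ge) else float("nan")
        for name, v in (("sigma2_G", s2_G_c), ("sigma2_GE", s2_GE_c)):
            if math.isfinite(v) and v < 0:
                truncated = True
                logger.info("variance_components: %s < 0 truncated to 0", name)
        s2_G = max(s2_G_c, 0.0) if math.isfinite(s2_G_c) else s2_G_c
        s2_GE = max(s2_GE_c, 0.0) if math.isfinite(s2_GE_c) else s2_GE_c

    return VarianceComponents(s2_G, s2_E, s2_GE, s2_eps, truncated=truncated)


def broad_sense_h2(components: VarianceComponents, e: int, r_reps: int) -> float:
    """H2 on a genotype-mean basis; NaN when undefined (never silently 0)."""
    if e < 1 or r_reps < 1:
        raise InvalidParameterError("e and r_reps must be >= 1")
    s2_G, s2_GE, s2_eps = components.sigma2_G, components.sigma2_GE, components.sigma2_eps
    if not all(math.isfinite(v) for v in (s2_G, s2_GE, s2_eps)):
        return float("nan")
    denom = s2_G + s2_GE / e + s2_eps / (r_reps * e)
    if denom == 0:
        return float("nan")
    return s2_G / denom


def h2_for_cells(
    cells: pd.DataFrame,
    value_col: str = "value",
    group: str = "all",
    ems_correction: bool = False,
) -> HeritabilityResult:
    """Effects -> components -> H2 for one balanced phenotype table."""
    eff = estimate_effects(cells, value_col=value_col)
    comp = variance_components(eff, ems_correction=ems_correction)
    h2 = broad_sense_h2(comp, eff.e, eff.r_reps)
    return HeritabilityResult(
        H2=h2,
        components=comp,
        g=eff.g,
        e=eff.e,
        r_reps=eff.r_reps,
        n_varieties_used=eff.g,
        group=group,
    )


# ---------------------------------------------------------------------------
# grouped heritability with the variety-completeness rule
# ---------------------------------------------------------------------------


def _qualifying(
    stage_df: pd.DataFrame, in_group: np.ndarray, e: int, r_reps: int
) -> list[str]:
    """Varieties whose full e*r plot set at this stage satisfies the condition."""
    df = stage_df.assign(_ok=in_group)
    agg = df.groupby("genotype")["_ok"].agg(["sum", "count"])
    full = agg[(agg["count"] == e * r_reps) & (agg["sum"] == e * r_reps)]
    return full.index.tolist()


def h2_by_group(
    table: pd.DataFrame,
    source: str,
    scheme: GroupingScheme | None = None,
    *,
    gls_ceiling: float = 0.82,
    restrict_to_eligible: bool | None = None,
    min_varieties: int = 2,
    ems_correction: bool = False,
) -> dict[str, HeritabilityResult]:
    """Heritability of one source's heights per subgroup.

    ``table`` is wide per plot observation with columns ``plot_id, stage,
    genotype, treatment, replicate, FM, lai`` and the source columns.  A
    variety enters a group (at a given stage) only when ALL of its e*r plots
    satisfy the group condition — partial varieties are excluded entirely,
    keeping the design balanced.  The GLS ceiling restriction (all plots'
    measured height below 0.82 m) applies by default only when ``source`` is
    GLS; pass ``restrict_to_eligible=True`` to impose it everywhere.

    Stages are decomposed separately (stage means dominate raw height
    variance) and a group's H2 is the unweighted mean over stages with at
    least ``min_varieties`` qualifying varieties; groups with none are
    undefined (NaN H2 — a "-" cell in a summary table).
    """
    if source not in table.columns:
        raise ConfigError([f"h2_by_group: source {source!r} not in table"])
    if restrict_to_eligible is None:
        restrict_to_eligible = source == "GLS"

    e = int(table["treatment"].nunique())
    r_reps = int(table["replicate"].nunique())
    stages = list(dict.fromkeys(table["stage"]))

    if scheme is None:
        groups: dict[str, np.ndarray] = {"all": np.ones(len(table), dtype=bool)}
    elif scheme.variable == "GS":
        labels = assign_groups(table["stage"].to_numpy(), scheme)
        groups = {name: labels == name for name in scheme.names}
    else:
        values = table["FM"] if scheme.variable == "CH" else table["lai"]
        labels = assign_groups(values.to_numpy(), scheme)
        groups = {name: labels == name for name in scheme.names}

    condition_base = np.ones(len(table), dtype=bool)
    if restrict_to_eligible:
        condition_base &= gls_eligibility(table["FM"].to_numpy(), gls_ceiling)
    condition_base &= table[source].notna().to_numpy()

    results: dict[str, HeritabilityResult] = {}
    for gname, in_group in groups.items():
        cond = in_group & condition_base
        per_stage: list[HeritabilityResult] = []
        used = 0
        for stage in stages:
            stage_mask = (table["stage"] == stage).to_numpy()
            stage_df = table.loc[stage_mask]
            varieties = _qualifying(stage_df, cond[stage_mask], e, r_reps)
            if len(varieties) < min_varieties:
                continue
            cells = stage_df[stage_df["genotype"].isin(varieties)]
            res = h2_for_cells(
                cells.rename(columns={source: "value"}),
                group=f"{gname}/{stage}",
                ems_correction=ems_correction,
            )
            per_stage.append(res)
            used = max(used, res.n_varieties_used)
        if per_stage:
            h2_vals = [r_.H2 for r_ in per_stage if math.isfinite(r_.H2)]
            h2 = float(np.mean(h2_vals)) if h2_vals else float("nan")
            results[gname] = HeritabilityResult(
                H2=h2,
                components=per_stage[0].components,
                g=used,
                e=e,
                r_reps=r_reps,
                n_varieties_used=used,
                group=gname,
            )
        else:
            results[gname] = HeritabilityResult(
                H2=float("nan"),
                components=None,
                g=0,
                e=e,
                r_reps=r_reps,
                n_varieties_used=0,
                group=gname,
            )
    return results
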