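"""Variance components and H2: hand decompositions, ANOVA cross-check, rules."""

import math

import numpy as np
import pandas as pd
import pytest

from canoheight.accuracy_compare import GroupingScheme
from canoheight.errors import IncompleteDesignError
from canoheight.heritability import (
    VarianceComponents,
    broad_sense_h2,
    estimate_effects,
    h2_by_group,
    h2_for_cells,
    variance_components,
)


def _cells(values_by_cell, r_reps=2):
    """Build a balanced table from {(genotype, treatment): [replicate values]}."""
    rows = []
    for (gn, tr), vals in values_by_cell.items():
        for k, v in enumerate(vals, 1):
            rows.append({"genotype": gn, "treatment": tr, "replicate": k, "value": v})
    return pd.DataFrame(rows)


def _random_cells(rng, g=6, e=2, r=2, mu=0.7, sg=0.1, sge=0.05, se=0.04):
    rows = []
    G = rng.normal(0, sg, g)
    E = rng.normal(0, 0.03, e)
    GE = rng.normal(0, sge, (g, e))
    for i in range(g):
        for j in range(e):
            for k in range(r):
                rows.append(
                    {
                        "genotype": f"V{i}",
                        "treatment": f"T{j}",
                        "replicate": k + 1,
                        "value": mu + G[i] + E[j] + GE[i, j] + rng.normal(0, se),
                    }
                )
    return pd.DataFrame(rows)


class TestEffects:
    def test_all_equal_gives_zero_effects(self):
        cells = _cells({("A", "N0"): [1, 1], ("A", "N1"): [1, 1],
                        ("B", "N0"): [1, 1], ("B", "N1"): [1, 1]})
        eff = estimate_effects(cells)
        assert np.allclose(eff.G, 0) and np.allclose(eff.E, 0)
        assert np.allclose(eff.GE.to_numpy(), 0) and np.allclose(eff.residuals, 0)

    def test_hand_two_way_decomposition(self):
        # genotype A sits +1 above the grand mean, B -1; no interaction/residual
        cells = _cells({("A", "N0"): [3, 3], ("A", "N1"): [3, 3],
                        ("B", "N0"): [1, 1], ("B", "N1"): [1, 1]})
        eff = estimate_effects(cells)
        assert eff.grand_mean == pytest.approx(2.0)
        assert dict(eff.G) == {"A": pytest.approx(1.0), "B": pytest.approx(-1.0)}
        assert np.allclose(eff.E, 0) and np.allclose(eff.GE.to_numpy(), 0)

    def test_margins_sum_to_zero(self, rng):
        eff = estimate_effects(_random_cells(rng))
        assert eff.G.sum() == pytest.approx(0, abs=1e-12)
        assert eff.E.sum() == pytest.approx(0, abs=1e-12)
        assert np.allclose(eff.GE.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(eff.GE.sum(axis=1), 0, atol=1e-12)

    def test_exact_reconstruction(self, rng):
        cells = _random_cells(rng)
        eff = estimate_effects(cells)
        rebuilt = (
            eff.grand_mean
            + cells["genotype"].map(eff.G).to_numpy()
            + cells["treatment"].map(eff.E).to_numpy()
            + np.array([eff.GE.loc[gn, tr] for gn, tr in zip(cells["genotype"], cells["treatment"])])
            + eff.residuals
        )
        assert np.allclose(rebuilt, cells["value"], atol=1e-12)

    def test_unbalanced_design_rejected(self, rng):
        cells = _random_cells(rng).iloc[:-1]  # drop one replicate
        with pytest.raises(IncompleteDesignError):
            estimate_effects(cells)

    def test_missing_value_rejected(self, rng):
        cells = _random_cells(rng)
        cells.loc[0, "value"] = np.nan
        with pytest.raises(IncompleteDesignError):
            estimate_effects(cells)


class TestVarianceComponents:
    def test_two_genotype_effect_sum(self):
        cells = _cells({("A", "N0"): [3, 3], ("A", "N1"): [3, 3],
                        ("B", "N0"): [1, 1], ("B", "N1"): [1, 1]})
        comp = variance_components(estimate_effects(cells))
        assert comp.sigma2_G == pytest.approx(2.0)  # (1^2 + 1^2) / (2 - 1)
        assert comp.sigma2_eps == 0.0

    def test_single_replicate_has_undefined_residual(self):
        cells = _cells({("A", "N0"): [1.0], ("A", "N1"): [1.1],
                        ("B", "N0"): [0.9], ("B", "N1"): [1.0]}, r_reps=1)
        comp = variance_components(estimate_effects(cells))
        assert math.isnan(comp.sigma2_eps)

    def test_matches_statsmodels_anova(self, rng):
        """Independent route: two-way ANOVA mean squares from statsmodels."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = _random_cells(rng, g=8, e=2, r=3)
        eff = estimate_effects(cells)
        comp = variance_components(eff)
        fit = ols("value ~ C(genotype) * C(treatment)", data=cells).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        ms = anova["sum_sq"] / anova["df"]
        e, r = eff.e, eff.r_reps
        assert comp.sigma2_G == pytest.approx(ms["C(genotype)"] / (e * r), rel=1e-9)
        assert comp.sigma2_GE == pytest.approx(ms["C(genotype):C(treatment)"] / r, rel=1e-9)
        assert comp.sigma2_eps == pytest.approx(ms["Residual"], rel=1e-9)

    def test_component_recovery_monte_carlo(self):
        # effect-sum genotype variance approximates var_G when only G varies
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            cells = _random_cells(rng, g=40, e=2, r=2, sg=0.1, sge=0.0, se=0.0)
            est.append(variance_components(estimate_effects(cells)).sigma2_G)
        assert np.mean(est) == pytest.approx(0.01, rel=0.15)


class TestBroadSenseH2:
    def test_eq_substitution(self):
        comp = VarianceComponents(4.0, 0.0, 2.0, 4.0)
        assert broad_sense_h2(comp, e=2, r_reps=2) == pytest.approx(4 / 6)

    def test_noiseless_limit(self):
        assert broad_sense_h2(VarianceComponents(0.5, 0, 0, 0), 2, 2) == 1.0

    def test_zero_genotypic_variance(self):
        assert broad_sense_h2(VarianceComponents(0.0, 0, 1.0, 1.0), 2, 2) == 0.0

    def test_undefined_when_component_missing(self):
        comp = VarianceComponents(1.0, 0.0, float("nan"), 0.5)
        assert math.isnan(broad_sense_h2(comp, 2, 2))

    def test_monotone_in_residual_variance(self):
        h2s = [broad_sense_h2(VarianceComponents(1.0, 0, 0.2, s), 2, 2) for s in (0, 0.5, 1, 2)]
        assert all(a > b for a, b in zip(h2s, h2s[1:]))

    def test_scale_invariance(self, rng):
        cells = _random_cells(rng)
        h2a = h2_for_cells(cells).H2
        cells2 = cells.assign(value=cells["value"] * 3.7)
        assert h2_for_cells(cells2).H2 == pytest.approx(h2a, rel=1e-9)


class TestGroupedH2:
    def _table(self, rng, g=8):
        rows = []
        G = rng.normal(0, 0.08, g)
        for i in range(g):
            for j, tr in enumerate(["N0", "N240"]):
                for k in (1, 2):
                    fm = 0.55 + G[i] + rng.normal(0, 0.02)
                    rows.append(
                        {
                            "plot_id": f"P{i}{j}{k}",
                            "stage": "heading",
                            "genotype": f"V{i:03d}",
                            "treatment": tr,
                            "replicate": k,
                            "FM": fm,
                            "lai": 3.0,
                            "TLS": fm + rng.normal(0, 0.005),
                        }
                    )
        return pd.DataFrame(rows)

    def test_partial_variety_excluded(self, rng):
        table = self._table(rng)
        scheme = GroupingScheme("CH", ("CH1", "CH2"), (0.3, 0.6, 0.8))
        # push one plot of variety V000 into CH2: V000 must leave CH1 entirely
        idx = table[table["genotype"] == "V000"].index[0]
        table.loc[idx, "FM"] = 0.75
        res = h2_by_group(table, "TLS", scheme)
        n_ch1 = res["CH1"].n_varieties_used
        all_in_ch1 = (table.groupby("genotype")["FM"].max() < 0.6).sum()
        assert n_ch1 == all_in_ch1
        assert n_ch1 < table["genotype"].nunique()

    def test_no_qualifying_varieties_undefined(self, rng):
        table = self._table(rng)
        scheme = GroupingScheme("CH", ("CH1", "CH4"), (0.3, 2.0, 5.0))
        res = h2_by_group(table, "TLS", scheme)
        assert math.isnan(res["CH4"].H2)  # the "-" cell
        assert res["CH4"].n_varieties_used == 0

    def test_gls_restriction_only_for_gls(self, rng):
        table = self._table(rng)
        table["GLS"] = table["TLS"]
        table.loc[table.index[:4], "FM"] = 1.0  # variety above the ceiling
        res_gls = h2_by_group(table, "GLS", None)
        res_tls = h2_by_group(table, "TLS", None)
        assert res_gls["all"].n_varieties_used < res_tls["all"].n_varieties_used
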