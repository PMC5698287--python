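"""Variance-component estimation: ANOVA/EMS oracle, REML, LRT."""

import numpy as np
import pandas as pd
import pytest

from wuequant.varcomp import (
    estimate_components_ems,
    fit_anova_balanced,
    fit_reml_bivariate,
    fit_reml_univariate,
    lrt_component,
    component_lrt,
    validate_balance,
)

from conftest import make_table


def _ems_triplet(table, trait="T"):
    design = validate_balance(table, trait)
    ems = estimate_components_ems(fit_anova_balanced(table, trait), design)
    return ems, design


class TestAnovaBalanced:
    def test_hand_anova_on_eight_values(self, two_by_two_table):
        """A=1, B=3 everywhere: all variation is genotypic, SS_G = 8."""
        an = fit_anova_balanced(two_by_two_table, "T")
        tab = an.table
        assert tab.loc["genotype", "ss"] == pytest.approx(8.0, abs=1e-12)
        for s in ("environment", "gxe", "error"):
            assert tab.loc[s, "ss"] == pytest.approx(0.0, abs=1e-12)
        assert tab["df"].sum() == 7  # N - 1

    def test_constant_data_gives_zero_ss(self):
        vals = {(g, e, r): 5.0 for g in "ABC" for e in ("E1", "E2")
                for r in (1, 2)}
        an = fit_anova_balanced(make_table(vals), "T")
        assert np.allclose(an.table["ss"], 0.0)

    def test_replicate_labels_are_exchangeable(self, balanced_sim):
        shuffled = balanced_sim.copy()
        swap = {"1": "2", "2": "1"}
        shuffled["replicate"] = shuffled["replicate"].map(swap)
        a = fit_anova_balanced(balanced_sim, "T").table
        b = fit_anova_balanced(shuffled, "T").table
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_statsmodels(self, balanced_sim):
        """Independent oracle: OLS sequential ANOVA on the same model."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        lm = smf.ols("value ~ C(genotype) * C(environment)",
                     data=balanced_sim).fit()
        ref = sm.stats.anova_lm(lm, typ=1)
        an = fit_anova_balanced(balanced_sim, "T").table
        assert an.loc["genotype", "ss"] == pytest.approx(
            ref.loc["C(genotype)", "sum_sq"])
        assert an.loc["environment", "ss"] == pytest.approx(
            ref.loc["C(environment)", "sum_sq"])
        assert an.loc["gxe", "ss"] == pytest.approx(
            ref.loc["C(genotype):C(environment)", "sum_sq"])
        assert an.loc["error", "ss"] == pytest.approx(
            ref.loc["Residual", "sum_sq"])

    def test_unbalanced_data_directed_to_reml(self, balanced_sim):
        with pytest.raises(ValueError, match="REML"):
            fit_anova_balanced(balanced_sim.iloc[1:], "T")


class TestEmsComponents:
    def test_hand_ems_algebra(self, two_by_two_table):
        ems, _ = _ems_triplet(two_by_two_table)
        assert ems.sigma_g2 == pytest.approx(2.0, abs=1e-12)
        assert ems.sigma_ge2 == 0.0
        assert ems.sigma_e2 == 0.0

    def test_constant_data_all_zero(self):
        vals = {(g, e, r): 5.0 for g in "ABC" for e in ("E1", "E2")
                for r in (1, 2)}
        ems, _ = _ems_triplet(make_table(vals))
        assert ems.as_array() == pytest.approx([0.0, 0.0, 0.0])

    def test_negative_interaction_truncated_with_flag(self):
        # cell means identical (MS_GE = 0) but within-cell spread positive
        # (MS_err > 0): the unconstrained interaction component is negative
        vals = {}
        for gi, g in enumerate("ABCD"):
            for e in ("E1", "E2"):
                vals[(g, e, 1)] = gi + 1.0
                vals[(g, e, 2)] = gi - 1.0
        ems, _ = _ems_triplet(make_table(vals))
        assert ems.unconstrained["sigma_ge2"] < 0.0
        assert ems.sigma_ge2 == 0.0
        assert "sigma_ge2" in ems.boundary


class TestRemlUnivariate:
    def test_matches_ems_on_balanced_interior_data(self, balanced_sim):
        """On balanced data the REML optimum is the closed-form EMS solution."""
        ems, _ = _ems_triplet(balanced_sim)
        assert min(ems.unconstrained.values()) > 0
        vc = fit_reml_univariate(balanced_sim, "T", init="equal")
        ref = np.array(list(ems.unconstrained.values()))
        assert np.max(np.abs(vc.as_array() - ref) / ref) < 1e-6

    def test_constant_data_flagged_degenerate(self):
        vals = {(g, e, r): 5.0 for g in "ABC" for e in ("E1", "E2")
                for r in (1, 2)}
        vc = fit_reml_univariate(make_table(vals), "T")
        assert vc.degenerate
        assert vc.sigma_g2 == 0.0 and vc.sigma_ge2 == 0.0

    def test_single_missing_plant_tolerated(self, balanced_sim):
        full = fit_reml_univariate(balanced_sim, "T", init="equal")
        vc = fit_reml_univariate(balanced_sim.iloc[1:], "T", init="equal")
        assert np.isfinite(vc.loglik)
        # one plant out of 120 barely moves the estimates
        assert np.allclose(vc.as_array(), full.as_array(), atol=0.3)

    def test_scale_equivariance(self, balanced_sim):
        """Scaling the trait by c scales every component by c^2."""
        c = 3.7
        scaled = balanced_sim.copy()
        scaled["value"] *= c
        a = fit_reml_univariate(balanced_sim, "T", init="moment").as_array()
        b = fit_reml_univariate(scaled, "T", init="moment").as_array()
        assert np.allclose(b, c ** 2 * a, rtol=1e-6)

    def test_two_genotypes_required(self):
        vals = {("A", e, r): float(r) for e in ("E1", "E2") for r in (1, 2)}
        with pytest.raises(ValueError, match="2 genotypes"):
            fit_reml_univariate(make_table(vals), "T")

    def test_asy_cov_is_psd(self, balanced_sim):
        vc = fit_reml_univariate(balanced_sim, "T")
        w = np.linalg.eigvalsh(vc.asy_cov)
        assert w.min() > -1e-12 * max(w.max(), 1.0)


class TestRemlBivariate:
    def test_duplicated_trait_gives_self_covariance(self, balanced_sim):
        dup = balanced_sim.copy()
        dup["trait"] = "T2"
        cc = fit_reml_bivariate(pd.concat([balanced_sim, dup]), "T", "T2")
        for stratum in ("genotype", "gxe", "residual"):
            v = cc.vc1.as_array()[("genotype", "gxe", "residual").index(stratum)]
            assert cc.cov(stratum) == pytest.approx(v, rel=1e-6, abs=1e-9)

    def test_sign_flip(self, balanced_sim):
        neg = balanced_sim.copy()
        neg["trait"] = "T2"
        neg["value"] = -neg["value"]
        cc = fit_reml_bivariate(pd.concat([balanced_sim, neg]), "T", "T2")
        assert cc.cov_g == pytest.approx(-cc.vc1.sigma_g2, rel=1e-6)
        assert cc.cov_e == pytest.approx(-cc.vc1.sigma_e2, rel=1e-6)

    def test_polarization_identity(self, bivariate_sim):
        """cov_x = [var_x(T1+T2) - var_x(T1-T2)] / 4 from univariate fits.

        The identity requires an interior optimum: a stratum pinned to the
        PSD boundary is constrained differently in the two constructions.
        """
        cc = fit_reml_bivariate(bivariate_sim, "T1", "T2", init="equal")
        assert not any(f.endswith("_singular") for f in cc.flags)
        wide = bivariate_sim.pivot_table(
            index=["genotype", "environment", "replicate"],
            columns="trait", values="value").reset_index()
        for name, vals in (("S", wide["T1"] + wide["T2"]),
                           ("D", wide["T1"] - wide["T2"])):
            wide[name] = vals
        long = wide.melt(
            id_vars=["genotype", "environment", "replicate"],
            value_vars=["S", "D"], var_name="trait", value_name="value")
        vs = fit_reml_univariate(long, "S", init="equal").as_array()
        vd = fit_reml_univariate(long, "D", init="equal").as_array()
        pol = (vs - vd) / 4.0
        est = np.array([cc.cov_g, cc.cov_ge, cc.cov_e])
        assert np.max(np.abs(est - pol)) < 1e-6

    def test_cross_scale_equivariance(self, bivariate_sim):
        """Scaling one trait by c scales the covariances by c."""
        c = 2.5
        scaled = bivariate_sim.copy()
        scaled.loc[scaled["trait"] == "T2", "value"] *= c
        a = fit_reml_bivariate(bivariate_sim, "T1", "T2", init="moment")
        b = fit_reml_bivariate(scaled, "T1", "T2", init="moment")
        assert b.cov_g == pytest.approx(c * a.cov_g, rel=1e-5)
        assert b.cov_e == pytest.approx(c * a.cov_e, rel=1e-5)

    def test_disjoint_traits_rejected(self, balanced_sim):
        other = balanced_sim.copy()
        other["trait"] = "T2"
        other["genotype"] = other["genotype"] + "_x"
        with pytest.raises(ValueError, match="share no"):
            fit_reml_bivariate(pd.concat([balanced_sim, other]), "T", "T2")


class TestLikelihoodRatioTest:
    def test_equal_likelihoods(self):
        res = lrt_component(-100.0, -100.0)
        assert res.statistic == 0.0
        assert res.p_mixture == 1.0

    def test_mixture_reference_critical_value(self):
        """Half the chi2_1 tail: statistic 2.706 sits at p ~= 0.05."""
        res = lrt_component(-100.0, -101.353)
        assert res.p_mixture == pytest.approx(0.05, abs=1e-3)

    def test_naive_reference_critical_value(self):
        res = lrt_component(-100.0, -101.9205)
        assert res.p_naive == pytest.approx(0.05, abs=1e-3)

    def test_reduced_better_than_full_is_an_error(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            lrt_component(-105.0, -100.0)

    def test_genotype_component_detected(self, balanced_sim):
        res = component_lrt(balanced_sim, "T", "genotype", init="moment")
        assert res.statistic > 0.0
        assert res.p_mixture < 0.05
        assert res.p_mixture == pytest.approx(res.p_naive / 2.0)


class TestValidateBalance:
    def test_complete_design(self, balanced_sim):
        d = validate_balance(balanced_sim, "T")
        assert (d.g, d.t, d.r, d.balanced) == (30, 2, 2, True)
        assert d.missing_cells == []

    def test_one_observation_removed(self, balanced_sim):
        d = validate_balance(balanced_sim.iloc[1:], "T")
        assert not d.balanced

    def test_missing_cell_listed(self, balanced_sim):
        mask = ~((balanced_sim["genotype"] == "G001")
                 & (balanced_sim["environment"] == "E1"))
        d = validate_balance(balanced_sim[mask], "T")
        assert not d.balanced
        assert ("G001", "E1") in d.missing_cells

    def test_ragged_replication_reports_minimum(self, balanced_sim):
        extra = balanced_sim.iloc[[0]].copy()
        extra["replicate"] = "3"
        with pytest.warns(UserWarning, match="ragged"):
            d = validate_balance(pd.concat([balanced_sim, extra]), "T")
        assert d.r == 2
        assert not d.balanced
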