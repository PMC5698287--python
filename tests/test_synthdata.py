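"""Synthetic-data generator: determinism, moments, calibration, raw layer."""

import numpy as np
import pandas as pd
import pytest

from wuequant.quantgen import correlations_from_components, heritability_mean_basis
from wuequant.synthdata import (
    RawSimulationConfig,
    SimulationConfig,
    components_from_h2,
    default_raw_config,
    default_ril_config,
    simulate_raw_experiment,
    simulate_trait_table,
)
from wuequant.traits import derive_trait_table
from wuequant.varcomp import (
    estimate_components_ems,
    fit_anova_balanced,
    fit_reml_bivariate,
    validate_balance,
)


def tiny_config(**kw):
    base = dict(
        n_genotypes=4, n_environments=2, n_replicates=2,
        trait_names=["T"], mu=np.array([10.0]),
        env_effects=np.array([[0.0], [1.0]]),
        Sigma_g=np.eye(1), Sigma_ge=np.eye(1) * 0.5, Sigma_e=np.eye(1) * 2.0,
        seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTraitTable:
    def test_same_seed_identical_tables(self):
        a = simulate_trait_table(tiny_config())
        b = simulate_trait_table(tiny_config())
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_noiseless_case_reduces_to_fixed_effects(self):
        cfg = tiny_config(Sigma_g=np.zeros((1, 1)),
                          Sigma_ge=np.zeros((1, 1)),
                          Sigma_e=np.zeros((1, 1)))
        t = simulate_trait_table(cfg)
        expected = t["environment"].map({"E1": 10.0, "E2": 11.0})
        assert np.allclose(t["value"], expected)

    def test_non_psd_matrix_named_in_error(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="Sigma_ge"):
            SimulationConfig(
                n_genotypes=4, n_environments=2, n_replicates=2,
                trait_names=["A", "B"], mu=np.zeros(2),
                env_effects=np.zeros((2, 2)), Sigma_g=np.eye(2),
                Sigma_ge=bad, Sigma_e=np.eye(2), seed=0)

    def test_moment_matching_at_large_g(self):
        """EMS components converge to the configured variances as g grows.

        Each component is checked against four analytic standard errors of
        its EMS estimator (the genotype and interaction strata carry only
        g-1 and (g-1)(t-1) degrees of freedom, so their sampling SD at
        g=2000 is several percent; the residual is far tighter).
        """
        sg, sge, se = 2.0, 1.0, 4.0
        g, t_, r = 2000, 2, 2
        cfg = tiny_config(n_genotypes=g, Sigma_g=np.eye(1) * sg,
                          Sigma_ge=np.eye(1) * sge, Sigma_e=np.eye(1) * se,
                          seed=11)
        tab = simulate_trait_table(cfg)
        d = validate_balance(tab, "T")
        ems = estimate_components_ems(fit_anova_balanced(tab, "T"), d)
        lam_g = se + r * sge + r * t_ * sg
        lam_ge = se + r * sge
        v_msg = 2 * lam_g ** 2 / (g - 1)
        v_msge = 2 * lam_ge ** 2 / ((g - 1) * (t_ - 1))
        v_mse = 2 * se ** 2 / (g * t_ * (r - 1))
        sd = np.sqrt([(v_msg + v_msge) / (r * t_) ** 2,
                      (v_msge + v_mse) / r ** 2,
                      v_mse])
        err = np.abs(ems.as_array() - [sg, sge, se])
        assert np.all(err < 4.0 * sd)
        assert ems.sigma_e2 == pytest.approx(se, rel=0.05)

    def test_missing_mask_keeps_every_cell(self):
        cfg = tiny_config(n_genotypes=40, n_replicates=3,
                          missing_fraction=0.3, seed=3)
        t = simulate_trait_table(cfg)
        counts = t.groupby(["genotype", "environment"]).size()
        assert len(counts) == 40 * 2        # no cell fully removed
        assert counts.min() >= 1
        assert len(t) < 40 * 2 * 3          # but some observations dropped

    def test_subset_preserves_marginals(self):
        cfg = default_ril_config(seed=4)
        sub = cfg.subset(["TE_s", "LMF_s"])
        i, j = cfg.trait_names.index("TE_s"), cfg.trait_names.index("LMF_s")
        assert sub.Sigma_g[0, 1] == cfg.Sigma_g[i, j]
        assert sub.mu[0] == cfg.mu[i]
        full = simulate_trait_table(cfg)
        part = simulate_trait_table(sub)
        assert set(part["trait"]) == {"TE_s", "LMF_s"}
        assert len(part) == len(full) // len(cfg.trait_names) * 2

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.trait_names == cfg.trait_names
        assert np.allclose(back.Sigma_g, cfg.Sigma_g)
        pd.testing.assert_frame_equal(simulate_trait_table(back),
                                      simulate_trait_table(cfg))


class TestDefaultCalibration:
    # the heritabilities the default configuration is solved to reproduce
    TARGET_H2 = {"LMF_s": 0.86, "LAR_s": 0.74, "water_use_ml": 0.73,
                 "leaf_area_cm2": 0.63, "shoot_biomass_g": 0.60,
                 "TE_s": 0.52, "SLA": 0.36}

    def test_config_valid_and_deterministic(self):
        cfg = default_ril_config(seed=0)
        assert cfg.n_genotypes == 72 and cfg.n_environments == 2
        for M in (cfg.Sigma_g, cfg.Sigma_ge, cfg.Sigma_e):
            assert np.linalg.eigvalsh(M).min() >= -1e-12

    def test_back_solved_components_reproduce_target_h2(self):
        """Forward check: the h2 formula recovers the calibration targets."""
        from wuequant.varcomp import VarianceComponents

        cfg = default_ril_config()
        for trait, target in self.TARGET_H2.items():
            i = cfg.trait_names.index(trait)
            vc = VarianceComponents(
                trait=trait, sigma_g2=cfg.Sigma_g[i, i],
                sigma_ge2=cfg.Sigma_ge[i, i], sigma_e2=cfg.Sigma_e[i, i],
                loglik=np.nan, asy_cov=np.zeros((3, 3)), method="EMS")
            h = heritability_mean_basis(vc, t=2, r=2)
            assert h.h2 == pytest.approx(target, abs=1e-9)

    def test_calibrated_genotypic_correlation(self):
        cfg = default_ril_config()
        i, j = cfg.trait_names.index("TE_s"), cfg.trait_names.index("LMF_s")
        rg = cfg.Sigma_g[i, j] / np.sqrt(cfg.Sigma_g[i, i] * cfg.Sigma_g[j, j])
        assert rg == pytest.approx(-0.55, abs=1e-12)

    def test_simulated_means_match_targets(self):
        cfg = default_ril_config(seed=21, n_genotypes=400)
        t = simulate_trait_table(cfg)
        te = t[(t["trait"] == "TE_s") & (t["environment"] == "E1")]["value"]
        assert te.mean() == pytest.approx(3.03, abs=0.05)

    def test_components_from_h2_rejects_bad_h2(self):
        with pytest.raises(ValueError):
            components_from_h2(1.0, 0.0, 2, 2, 0.25)


class TestRawLayer:
    def test_zero_noise_round_trip(self):
        """Derived traits reproduce the latent truth without measurement noise."""
        raw = simulate_raw_experiment(default_raw_config(seed=13, n_genotypes=6))
        derived = derive_trait_table(raw.plants, raw.water, raw.evaporation)
        merged = derived.merge(
            raw.latent_traits,
            on=["genotype", "environment", "replicate", "trait"],
            suffixes=("_derived", "_latent"))
        assert len(merged) == len(raw.latent_traits)
        err = (merged["value_derived"] - merged["value_latent"]).abs().max()
        assert err < 1e-9

    def test_fractions_sum_to_one_by_construction(self):
        raw = simulate_raw_experiment(default_raw_config(seed=14, n_genotypes=5))
        fr = raw.latent_traits[
            raw.latent_traits["trait"].isin(["LMF_wp", "SMF_wp", "RMF_wp"])]
        sums = fr.groupby(["genotype", "environment", "replicate"])["value"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_same_seed_identical_outputs(self):
        a = simulate_raw_experiment(default_raw_config(seed=15, n_genotypes=4))
        b = simulate_raw_experiment(default_raw_config(seed=15, n_genotypes=4))
        pd.testing.assert_frame_equal(a.plants, b.plants)
        pd.testing.assert_frame_equal(a.water, b.water)

    def test_measurement_noise_perturbs_but_preserves_positivity(self):
        cfg = default_raw_config(seed=16, n_genotypes=5)
        cfg.mass_noise_sd = 0.05
        cfg.area_noise_sd = 5.0
        cfg.water_noise_sd = 2.0
        raw = simulate_raw_experiment(cfg)
        assert (raw.plants[["leaf_mass_g", "stem_mass_g", "root_mass_g",
                            "leaf_area_cm2"]] > 0).all().all()
        assert (raw.water["water_ml"] >= 0).all()
        derived = derive_trait_table(raw.plants, raw.water, raw.evaporation)
        merged = derived.merge(
            raw.latent_traits,
            on=["genotype", "environment", "replicate", "trait"])
        assert (merged["value_x"] != merged["value_y"]).any()

    def test_infeasible_calibration_raises(self):
        cfg = default_raw_config(seed=17, n_genotypes=4)
        cfg.latent.Sigma_e = np.diag([0.1, 0.02, 0.02, 0.02, 50.0, 1e6])
        with pytest.raises(RuntimeError, match="redraw"):
            simulate_raw_experiment(cfg)

    def test_genotypic_correlation_survives_inversion(self):
        """TE/LMF genotypic correlation propagates through the raw layer.

        25 replicates; the bound is four Monte-Carlo standard errors
        around the configured -0.55.
        """
        vals = []
        for s in range(25):
            raw = simulate_raw_experiment(default_raw_config(seed=500 + s))
            derived = derive_trait_table(raw.plants, raw.water, raw.evaporation)
            cc = fit_reml_bivariate(derived, "TE_wp", "LMF_wp", init="moment")
            vals.append(correlations_from_components(cc, 2, 2).r_g)
        vals = np.asarray(vals)
        bound = 4.0 * vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-0.55)) < max(bound, 0.05)

    def test_latent_trait_names_enforced(self):
        cfg = default_raw_config()
        with pytest.raises(ValueError, match="latent traits"):
            RawSimulationConfig(latent=cfg.latent.subset(["TE_wp", "SLA"]))
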