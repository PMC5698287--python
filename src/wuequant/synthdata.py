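"""Synthetic genotype x environment phenotype data.

Two layers:

* trait level — draws long-format phenotype tables from the additive
  mixed model the analysis assumes: independent multivariate-normal
  genotypic, genotype x environment and residual effects around fixed
  trait-by-environment means;
* raw-measurement level — inverts latent whole-plant traits through the
  trait formulas into biomass compartments, leaf area and a daily
  water-use series, so that re-deriving traits from the emitted raw tables
  recovers the latent values exactly when measurement noise is zero.

The default calibration emulates a sunflower recombinant-inbred-line
water-use trial: 72 lines in two environments with two replicates, trait
means and heritabilities typical of such trials, and a negative genotypic
correlation (-0.55) between shoot transpiration efficiency and leaf mass
fraction.  Stratum variances are back-solved from the target
heritabilities at t = r = 2, fixing the G x E to residual variance ratio
per trait (the one quantity the heritability does not pin down).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "RawSimulationConfig",
    "RawExperiment",
    "simulate_trait_table",
    "simulate_raw_experiment",
    "default_ril_config",
    "default_raw_config",
    "components_from_h2",
]


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise ValueError(f"{name} is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")
    return M


@dataclass
class SimulationConfig:
    """Design sizes, trait means and stratum covariances for the generator."""

    n_genotypes: int
    n_environments: int
    n_replicates: int
    trait_names: list[str]
    mu: np.ndarray                # m means
    env_effects: np.ndarray       # t x m fixed offsets
    Sigma_g: np.ndarray           # m x m genotypic covariance
    Sigma_ge: np.ndarray          # m x m G x E covariance
    Sigma_e: np.ndarray           # m x m residual covariance
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        m = len(self.trait_names)
        self.mu = np.asarray(self.mu, dtype=float)
        self.env_effects = np.asarray(self.env_effects, dtype=float)
        if self.mu.shape != (m,):
            raise ValueError("mu must have one entry per trait")
        if self.env_effects.shape != (self.n_environments, m):
            raise ValueError("env_effects must be t x m")
        for name in ("Sigma_g", "Sigma_ge", "Sigma_e"):
            setattr(self, name, _check_psd(getattr(self, name), name))
            if getattr(self, name).shape != (m, m):
                raise ValueError(f"{name} must be {m} x {m}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if min(self.n_genotypes, self.n_replicates) < 2 or self.n_environments < 1:
            raise ValueError("need >= 2 genotypes, >= 1 environment, >= 2 replicates")

    def subset(self, traits: list[str]) -> "SimulationConfig":
        """Restrict the configuration to a subset of traits."""
        idx = [self.trait_names.index(t) for t in traits]
        sub = np.ix_(idx, idx)
        return SimulationConfig(
            n_genotypes=self.n_genotypes,
            n_environments=self.n_environments,
            n_replicates=self.n_replicates,
            trait_names=list(traits),
            mu=self.mu[idx],
            env_effects=self.env_effects[:, idx],
            Sigma_g=self.Sigma_g[sub],
            Sigma_ge=self.Sigma_ge[sub],
            Sigma_e=self.Sigma_e[sub],
            missing_fraction=self.missing_fraction,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, np.ndarray):
                data[k] = v.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for k in ("mu", "env_effects", "Sigma_g", "Sigma_ge", "Sigma_e"):
            data[k] = np.asarray(data[k], dtype=float)
        return cls(**data)


def simulate_trait_table(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a long-format phenotype table from the additive mixed model.

    y_ijkm = mu_m + E_jm + G_im + GE_ijm + eps_ijkm with rows of G, GE and
    eps independent multivariate normal.  The output is balanced unless
    ``missing_fraction`` > 0, in which case observations are masked per
    genotype x environment cell but never a whole cell, as long as
    ``missing_fraction`` <= (r-1)/r.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g, t, r = config.n_genotypes, config.n_environments, config.n_replicates
    m = len(config.trait_names)
    G = rng.multivariate_normal(np.zeros(m), config.Sigma_g, size=g,
                                method="svd")
    GE = rng.multivariate_normal(np.zeros(m), config.Sigma_ge, size=g * t,
                                 method="svd")
    eps = rng.multivariate_normal(np.zeros(m), config.Sigma_e, size=g * t * r,
                                  method="svd")
    gi = np.repeat(np.arange(g), t * r)
    ei = np.tile(np.repeat(np.arange(t), r), g)
    ri = np.tile(np.arange(r), g * t)
    Y = (config.mu[None, :] + config.env_effects[ei] + G[gi]
         + GE[gi * t + ei] + eps)
    geno = np.array([f"G{i + 1:03d}" for i in range(g)])
    env = np.array([f"E{j + 1}" for j in range(t)])
    frames = []
    for k, trait in enumerate(config.trait_names):
        frames.append(pd.DataFrame({
            "genotype": geno[gi],
            "environment": env[ei],
            "replicate": (ri + 1).astype(str),
            "trait": trait,
            "value": Y[:, k],
        }))
    table = pd.concat(frames, ignore_index=True)
    if config.missing_fraction > 0.0:
        keep = np.ones(g * t * r, dtype=bool)
        cap = r - 1 if config.missing_fraction <= (r - 1) / r else r
        for cell_start in range(0, g * t * r, r):
            drop = rng.random(r) < config.missing_fraction
            if drop.sum() > cap:
                drop_idx = np.flatnonzero(drop)
                rng.shuffle(drop_idx)
                drop = np.zeros(r, dtype=bool)
                drop[drop_idx[:cap]] = True
            keep[cell_start:cell_start + r] = ~drop
        table = table[np.tile(keep, m)].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# calibration helpers

def components_from_h2(sigma_g2: float, h2: float, t: int, r: int,
                       ge_to_e: float) -> tuple[float, float]:
    """Back-solve (sigma_ge2, sigma_e2) from a genotypic variance and a
    target mean-basis heritability, fixing the ratio sigma_ge2 / sigma_e2.

    From h2 = sigma_g2 / (sigma_e2/(r t) + sigma_ge2/t + sigma_g2):
    sigma_e2 = sigma_g2 (1 - h2) / (h2 (k/t + 1/(r t))), k = ge_to_e.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if h2 == 1.0:
        return 0.0, 0.0
    sigma_e2 = sigma_g2 * (1.0 - h2) / (h2 * (ge_to_e / t + 1.0 / (r * t)))
    return ge_to_e * sigma_e2, sigma_e2


# Calibration table for the default RIL trial.  Per trait: mean, the span
# of predicted (shrunken) genotype means used to set the genotypic SD, the
# target mean-basis heritability at t = r = 2, the G x E : residual
# variance ratio (1.0 for the two traits where interaction is a dominant
# feature of such trials — shoot biomass and SLA — else 0.25), and the
# fixed offset of the second (water-deficit) environment.
_DEFAULT_TRAITS = {
    #  name              mean    blup_span        h2     ge/e   env2 offset
    "LMF_s":         (0.60,  (0.52, 0.67),   0.86,  0.25,  -0.03),
    "LAR_s":         (143.0, (116.0, 175.0), 0.74,  0.25,  -10.0),
    "water_use_ml":  (897.0, (472.0, 1303.0), 0.73, 0.25, -150.0),
    "leaf_area_cm2": (386.0, (225.0, 534.0), 0.63,  0.25,  -60.0),
    "shoot_biomass_g": (2.77, (1.55, 4.17),  0.60,  1.00,  -0.3),
    "TE_s":          (3.03,  (2.60, 3.67),   0.52,  0.25,   0.3),
    "SLA":           (237.0, (202.0, 286.0), 0.36,  1.00, -20.0),
}

# expected range of n iid standard normals, n = 72 (used to convert a span
# of predicted genotype means into a genotypic SD)
_RANGE_FACTOR_72 = 4.8

# the calibrated trait pair: genotypic and residual correlation between
# shoot transpiration efficiency and leaf mass fraction
_RG_TE_LMF = -0.55
_RE_TE_LMF = -0.25


def default_ril_config(seed: int = 0, *, n_genotypes: int = 72,
                       n_environments: int = 2, n_replicates: int = 2,
                       missing_fraction: float = 0.0) -> SimulationConfig:
    """Default trait-level configuration emulating a sunflower RIL trial.

    The span of predicted genotype means for trait k translates to a
    genotypic SD via span = 4.8 * sd(BLUP) and var(BLUP) = h2 * sigma_g2;
    G x E and residual variances are then back-solved from the target
    heritability.  Off-diagonal structure is limited to the calibrated
    TE_s / LMF_s pair; other traits are generated uncorrelated.
    """
    names = list(_DEFAULT_TRAITS)
    m = len(names)
    mu = np.array([_DEFAULT_TRAITS[k][0] for k in names])
    sg = np.empty(m)
    sge = np.empty(m)
    se = np.empty(m)
    t, r = n_environments, n_replicates
    for i, k in enumerate(names):
        mean, (lo, hi), h2, ratio, _ = _DEFAULT_TRAITS[k]
        sd_g = (hi - lo) / (_RANGE_FACTOR_72 * np.sqrt(h2))
        sg[i] = sd_g ** 2
        sge[i], se[i] = components_from_h2(sg[i], h2, 2, 2, ratio)
    Sigma_g = np.diag(sg)
    Sigma_ge = np.diag(sge)
    Sigma_e = np.diag(se)
    i_te, i_lmf = names.index("TE_s"), names.index("LMF_s")
    Sigma_g[i_te, i_lmf] = Sigma_g[i_lmf, i_te] = (
        _RG_TE_LMF * np.sqrt(sg[i_te] * sg[i_lmf]))
    Sigma_e[i_te, i_lmf] = Sigma_e[i_lmf, i_te] = (
        _RE_TE_LMF * np.sqrt(se[i_te] * se[i_lmf]))
    env_effects = np.zeros((t, m))
    for j in range(1, t):
        env_effects[j] = [_DEFAULT_TRAITS[k][4] for k in names]
    return SimulationConfig(
        n_genotypes=n_genotypes, n_environments=t, n_replicates=r,
        trait_names=names, mu=mu, env_effects=env_effects,
        Sigma_g=Sigma_g, Sigma_ge=Sigma_ge, Sigma_e=Sigma_e,
        missing_fraction=missing_fraction, seed=seed)


# ---------------------------------------------------------------------------
# raw-measurement layer

_LATENT = ["TE_wp", "LMF_wp", "SMF_wp", "RMF_wp", "SLA", "water_use_ml"]


@dataclass
class RawSimulationConfig:
    """Latent-trait generator plus measurement-noise and watering settings."""

    latent: SimulationConfig                 # over the six latent traits
    mass_noise_sd: float = 0.0               # g, additive on each compartment
    area_noise_sd: float = 0.0               # cm2
    water_noise_sd: float = 0.0              # mL, per day on pot loss
    evaporation_ml_day: float = 15.0         # direct soil evaporation level
    n_days: int = 12                         # length of the watering record
    n_evap_pots: int = 4
    max_redraw_fraction: float = 0.01

    def __post_init__(self):
        if list(self.latent.trait_names) != _LATENT:
            raise ValueError(f"latent traits must be {_LATENT}")
        if self.n_days < 1 or self.n_evap_pots < 1:
            raise ValueError("need at least one day and one evaporation pot")


@dataclass
class RawExperiment:
    """Raw CSV-shaped tables plus the latent truth for round-trip checks."""

    plants: pd.DataFrame        # plant_id, genotype, environment, replicate, masses, area
    water: pd.DataFrame         # plant_id, day, water_ml (uncorrected pot loss)
    evaporation: pd.DataFrame   # pot_id, day, water_ml
    latent_traits: pd.DataFrame  # long format, renormalized latent truth
    n_redraws: int = 0


def default_raw_config(seed: int = 0, *, n_genotypes: int = 24,
                       n_replicates: int = 2) -> RawSimulationConfig:
    """Raw-layer defaults: whole-plant trait means for a droughted RIL set.

    Means: TE_wp 4.8 g/L, mass fractions 0.45/0.33/0.22, SLA 237 cm2/g,
    water use 897 mL; genotypic correlation -0.55 between TE_wp and
    LMF_wp.  Variances are back-solved from mid-range heritabilities
    (0.55 for TE_wp, 0.8 for the fractions, 0.4 for SLA, 0.7 for water
    use) with the G x E : residual ratio fixed at 0.25.
    """
    mu = np.array([4.8, 0.45, 0.33, 0.22, 237.0, 897.0])
    cv_g = np.array([0.06, 0.05, 0.05, 0.08, 0.05, 0.12])
    h2 = np.array([0.55, 0.80, 0.80, 0.80, 0.40, 0.70])
    sg = (cv_g * mu) ** 2
    sge = np.empty(6)
    se = np.empty(6)
    for i in range(6):
        sge[i], se[i] = components_from_h2(sg[i], h2[i], 2, 2, 0.25)
    Sigma_g, Sigma_ge, Sigma_e = np.diag(sg), np.diag(sge), np.diag(se)
    Sigma_g[0, 1] = Sigma_g[1, 0] = -0.55 * np.sqrt(sg[0] * sg[1])
    env_effects = np.zeros((2, 6))
    env_effects[1] = [0.3, -0.02, 0.01, 0.01, -20.0, -120.0]
    latent = SimulationConfig(
        n_genotypes=n_genotypes, n_environments=2, n_replicates=n_replicates,
        trait_names=list(_LATENT), mu=mu, env_effects=env_effects,
        Sigma_g=Sigma_g, Sigma_ge=Sigma_ge, Sigma_e=Sigma_e, seed=seed)
    return RawSimulationConfig(latent=latent)


def simulate_raw_experiment(config: RawSimulationConfig,
                            rng: np.random.Generator | None = None) -> RawExperiment:
    """Emit raw per-plant tables whose derived traits equal the latent truth.

    Inversion order is fixed: mass fractions are renormalized to sum to
    one, total dry mass follows from TE_wp and water use, compartment
    masses from the fractions, leaf area from SLA, and the daily series
    spreads the latent water use over ``n_days`` with a deterministic
    ramp, adding the soil-evaporation level that the control pots record.
    Infeasible latent draws (non-positive mass, area or water use) redraw
    the plant's residual vector; more than ``max_redraw_fraction`` of
    plants redrawn is an error.
    """
    if rng is None:
        rng = np.random.default_rng(config.latent.seed)
    lat = config.latent
    g, t, r = lat.n_genotypes, lat.n_environments, lat.n_replicates
    m = len(_LATENT)
    G = rng.multivariate_normal(np.zeros(m), lat.Sigma_g, size=g, method="svd")
    GE = rng.multivariate_normal(np.zeros(m), lat.Sigma_ge, size=g * t,
                                 method="svd")
    n_plants = g * t * r
    n_redraws = 0
    plant_rows, water_rows, latent_rows = [], [], []
    # deterministic within-experiment watering profile: linear ramp
    profile = np.arange(1, config.n_days + 1, dtype=float)
    profile /= profile.sum()
    days = np.arange(1, config.n_days + 1)

    idx = 0
    for i in range(g):
        for j in range(t):
            for k in range(r):
                base = lat.mu + lat.env_effects[j] + G[i] + GE[i * t + j]
                for attempt in range(200):
                    vals = base + rng.multivariate_normal(
                        np.zeros(m), lat.Sigma_e, method="svd")
                    te, lmf, smf, rmf, sla, wu = vals
                    if (te > 0 and lmf > 0 and smf > 0 and rmf > 0
                            and sla > 0 and wu > 0):
                        break
                    n_redraws += 1
                else:
                    raise RuntimeError("could not draw a feasible plant")
                frac_sum = lmf + smf + rmf
                lmf, smf, rmf = lmf / frac_sum, smf / frac_sum, rmf / frac_sum
                water_l = wu / 1000.0
                total = te * water_l
                leaf, stem, root = lmf * total, smf * total, rmf * total
                area = sla * leaf
                daily = wu * profile + config.evaporation_ml_day
                if config.mass_noise_sd > 0:
                    leaf, stem, root = np.clip(
                        [leaf, stem, root]
                        + rng.normal(0, config.mass_noise_sd, 3), 1e-6, None)
                if config.area_noise_sd > 0:
                    area = max(area + rng.normal(0, config.area_noise_sd), 1e-6)
                if config.water_noise_sd > 0:
                    daily = np.clip(
                        daily + rng.normal(0, config.water_noise_sd,
                                           config.n_days), 0.0, None)
                idx += 1
                pid = f"P{idx:04d}"
                gid, eid, rid = f"G{i + 1:03d}", f"E{j + 1}", str(k + 1)
                plant_rows.append({
                    "plant_id": pid, "genotype": gid, "environment": eid,
                    "replicate": rid, "leaf_mass_g": leaf,
                    "stem_mass_g": stem, "root_mass_g": root,
                    "leaf_area_cm2": area,
                })
                water_rows.extend(
                    {"plant_id": pid, "day": int(d), "water_ml": float(w)}
                    for d, w in zip(days, daily))
                truth = {"TE_wp": te, "LMF_wp": lmf, "SMF_wp": smf,
                         "RMF_wp": rmf, "SLA": sla, "plant_water_use": water_l}
                latent_rows.extend(
                    {"genotype": gid, "environment": eid, "replicate": rid,
                     "trait": nm, "value": float(v)}
                    for nm, v in truth.items())
    if n_redraws > config.max_redraw_fraction * n_plants:
        raise RuntimeError(
            f"{n_redraws} residual redraws for {n_plants} plants exceeds "
            f"the allowed fraction {config.max_redraw_fraction}; the latent "
            "calibration is too wide for positivity")
    evap_rows = [
        {"pot_id": f"EV{p + 1}", "day": int(d),
         "water_ml": float(config.evaporation_ml_day)}
        for p in range(config.n_evap_pots) for d in days
    ]
    return RawExperiment(
        plants=pd.DataFrame(plant_rows),
        water=pd.DataFrame(water_rows),
        evaporation=pd.DataFrame(evap_rows),
        latent_traits=pd.DataFrame(latent_rows),
        n_redraws=n_redraws)
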