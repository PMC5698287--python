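"""Variance and covariance components for genotype x environment trials.

Two estimation routes are provided for the two-way mixed model
``y_ijk = mu + E_j + G_i + (GE)_ij + eps_ijk`` (environment fixed; genotype,
interaction and residual random):

* balanced-ANOVA expected mean squares (EMS) — closed form, balanced data
  only, useful as an independent oracle;
* REML via Fisher scoring with monotone EM fallback — the general route,
  which on balanced data with interior estimates reproduces the EMS
  solution.

Variance components of single traits, covariance components of trait
pairs (unstructured 2x2 blocks per stratum), and boundary-corrected
likelihood-ratio tests for single components are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import MvRemlFit, fit_mv_reml

__all__ = [
    "DesignInfo",
    "AnovaTable",
    "VarianceComponents",
    "CovarianceComponents",
    "LrtResult",
    "validate_balance",
    "fit_anova_balanced",
    "estimate_components_ems",
    "fit_reml_univariate",
    "fit_reml_bivariate",
    "lrt_component",
    "component_lrt",
]

STRATA = ("genotype", "gxe", "residual")
KEY = ["genotype", "environment", "replicate"]


@dataclass
class DesignInfo:
    """Design sizes of a genotype x environment trial.

    ``r`` is the replicate count per genotype x environment cell; for ragged
    designs it is reported as the minimum cell count with ``balanced=False``.
    """

    g: int
    t: int
    r: int
    balanced: bool
    missing_cells: list[tuple] = field(default_factory=list)


@dataclass
class AnovaTable:
    """Two-way ANOVA sums of squares with interaction and within-cell error."""

    table: pd.DataFrame  # index: genotype, environment, gxe, error; cols ss, df, ms
    trait: str

    def ms(self, stratum: str) -> float:
        return float(self.table.loc[stratum, "ms"])


@dataclass
class VarianceComponents:
    """Genotypic, G x E and residual variances for one trait.

    ``unconstrained`` keeps the raw method-of-moments values (which may be
    negative); the main fields are constrained to the non-negative orthant.
    ``asy_cov`` is the inverse expected information in the order
    (sigma_g2, sigma_ge2, sigma_e2).
    """

    trait: str
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    loglik: float
    asy_cov: np.ndarray
    method: str                       # "EMS" or "REML"
    unconstrained: dict[str, float] | None = None
    boundary: list[str] = field(default_factory=list)
    degenerate: bool = False
    n_iter: int = 0
    fit: MvRemlFit | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_g2, self.sigma_ge2, self.sigma_e2])

    @property
    def sigma_p2(self) -> float:
        """Individual-plant phenotypic variance."""
        return self.sigma_g2 + self.sigma_ge2 + self.sigma_e2


@dataclass
class CovarianceComponents:
    """Stratum covariances for a trait pair plus each trait's variances.

    ``asy_cov`` is the 9 x 9 joint asymptotic covariance in the order given
    by ``param_index``: for each stratum (genotype, gxe, residual) the
    triple (var_trait1, cov, var_trait2).
    """

    trait1: str
    trait2: str
    cov_g: float
    cov_ge: float
    cov_e: float
    vc1: VarianceComponents
    vc2: VarianceComponents
    loglik: float
    asy_cov: np.ndarray
    param_index: list[tuple[str, int, int]]
    flags: list[str] = field(default_factory=list)

    def cov(self, stratum: str) -> float:
        return {"genotype": self.cov_g, "gxe": self.cov_ge,
                "residual": self.cov_e}[stratum]


@dataclass
class LrtResult:
    """Boundary-corrected likelihood-ratio test of one variance component."""

    component: str
    statistic: float
    p_mixture: float   # 0.5 chi2_0 + 0.5 chi2_1 reference (boundary-correct)
    p_naive: float     # plain chi2_1 reference


# ---------------------------------------------------------------------------
# design handling

def _trait_frame(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    df = table[table["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    return df


def validate_balance(table: pd.DataFrame, trait: str | None = None) -> DesignInfo:
    """Infer (g, t, r) and balance; list missing genotype x environment cells."""
    df = _trait_frame(table, trait) if trait is not None else table
    g = df["genotype"].nunique()
    t = df["environment"].nunique()
    counts = df.groupby(["genotype", "environment"], observed=True).size()
    full = g * t
    missing = []
    if len(counts) < full:
        have = set(counts.index)
        for gv in df["genotype"].unique():
            for ev in df["environment"].unique():
                if (gv, ev) not in have:
                    missing.append((gv, ev))
    r_min, r_max = int(counts.min()), int(counts.max())
    balanced = (len(counts) == full) and (r_min == r_max)
    if not balanced and r_min != r_max:
        warnings.warn(
            f"ragged replication (r between {r_min} and {r_max}); "
            "reporting r as the minimum", stacklevel=2)
    return DesignInfo(g=g, t=t, r=r_min, balanced=balanced,
                      missing_cells=missing)


def _design_arrays(df: pd.DataFrame):
    """Observation vectors and incidence matrices for one trait's records."""
    g_lv, gi = np.unique(df["genotype"].to_numpy(), return_inverse=True)
    e_lv, ei = np.unique(df["environment"].to_numpy(), return_inverse=True)
    g, t = len(g_lv), len(e_lv)
    N = len(df)
    Zg = np.zeros((N, g))
    Zg[np.arange(N), gi] = 1.0
    Zge = np.zeros((N, g * t))
    Zge[np.arange(N), gi * t + ei] = 1.0
    X = np.zeros((N, t))
    X[np.arange(N), ei] = 1.0   # environment cell means (absorbs intercept)
    return df["value"].to_numpy(float), X, Zg, Zge, gi, ei, g_lv, e_lv


# ---------------------------------------------------------------------------
# ANOVA / EMS route

def fit_anova_balanced(table: pd.DataFrame, trait: str) -> AnovaTable:
    """Two-way (genotype, environment) ANOVA with interaction, balanced only."""
    df = _trait_frame(table, trait)
    design = validate_balance(table, trait)
    if not design.balanced:
        raise ValueError(
            "design is unbalanced; use fit_reml_univariate for the "
            "general REML route")
    if design.r < 2:
        raise ValueError("within-cell error requires r >= 2")
    y, X, Zg, Zge, gi, ei, _, _ = _design_arrays(df)
    g, t, r = design.g, design.t, design.r
    cell = gi * t + ei
    cell_mean = np.bincount(cell, weights=y) / r
    gm = cell_mean.reshape(g, t)
    g_mean = gm.mean(axis=1)
    e_mean = gm.mean(axis=0)
    grand = g_mean.mean()
    ss_g = r * t * np.sum((g_mean - grand) ** 2)
    ss_e = r * g * np.sum((e_mean - grand) ** 2)
    inter = gm - g_mean[:, None] - e_mean[None, :] + grand
    ss_ge = r * np.sum(inter ** 2)
    ss_err = np.sum((y - cell_mean[cell]) ** 2)
    rows = pd.DataFrame(
        {
            "ss": [ss_g, ss_e, ss_ge, ss_err],
            "df": [g - 1, t - 1, (g - 1) * (t - 1), g * t * (r - 1)],
        },
        index=pd.Index(["genotype", "environment", "gxe", "error"],
                       name="stratum"),
    )
    rows["ms"] = rows["ss"] / rows["df"]
    return AnovaTable(table=rows, trait=trait)


def estimate_components_ems(anova: AnovaTable, design: DesignInfo) -> VarianceComponents:
    """Closed-form expected-mean-squares components from a balanced ANOVA.

    sigma_e2 = MS_err; sigma_ge2 = (MS_GE - MS_err)/r;
    sigma_g2 = (MS_G - MS_GE)/(r t).  Negative solutions are truncated at
    zero with the raw values kept in ``unconstrained``.
    """
    if not design.balanced:
        raise ValueError("EMS estimators require a balanced design")
    r, t = design.r, design.t
    ms_err = anova.ms("error")
    ms_ge = anova.ms("gxe")
    ms_g = anova.ms("genotype")
    raw = {
        "sigma_g2": (ms_g - ms_ge) / (r * t),
        "sigma_ge2": (ms_ge - ms_err) / r,
        "sigma_e2": ms_err,
    }
    boundary = [k for k, v in raw.items() if v < 0.0]
    # sampling covariance of the linear-in-MS estimators:
    # var(MS_s) = 2 lambda_s^2 / df_s with independent strata
    lam = {
        "error": ms_err,
        "gxe": ms_ge,
        "genotype": ms_g,
    }
    dfs = {s: float(anova.table.loc[s, "df"]) for s in lam}
    v_ms = {s: 2.0 * max(lam[s], 0.0) ** 2 / dfs[s] for s in lam}
    A = np.array([
        [1.0 / (r * t), -1.0 / (r * t), 0.0],   # sigma_g2 from (MS_G, MS_GE, MS_err)
        [0.0, 1.0 / r, -1.0 / r],
        [0.0, 0.0, 1.0],
    ])
    D = np.diag([v_ms["genotype"], v_ms["gxe"], v_ms["error"]])
    asy_cov = A @ D @ A.T
    return VarianceComponents(
        trait=anova.trait,
        sigma_g2=max(raw["sigma_g2"], 0.0),
        sigma_ge2=max(raw["sigma_ge2"], 0.0),
        sigma_e2=max(raw["sigma_e2"], 0.0),
        loglik=np.nan,
        asy_cov=asy_cov,
        method="EMS",
        unconstrained=raw,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# REML route

def _strata_design(df, include: tuple[str, ...]):
    y, X, Zg, Zge, gi, ei, g_lv, e_lv = _design_arrays(df)
    Z_list, names = [], []
    if "genotype" in include:
        Z_list.append(Zg)
        names.append("genotype")
    if "gxe" in include:
        Z_list.append(Zge)
        names.append("gxe")
    return y, X, Z_list, tuple(names), gi, ei


def fit_reml_univariate(
    table: pd.DataFrame,
    trait: str,
    design: DesignInfo | None = None,
    *,
    include: tuple[str, ...] = ("genotype", "gxe"),
    init: str = "equal",
) -> VarianceComponents:
    """REML variance components for one trait.

    ``include`` lists the random strata besides the residual; dropping one
    gives the reduced models used by the likelihood-ratio tests.
    """
    df = _trait_frame(table, trait)
    if df["genotype"].nunique() < 2:
        raise ValueError("at least 2 genotypes are required")
    y, X, Z_list, names, gi, ei = _strata_design(df, include)
    fit = fit_mv_reml(y, X, Z_list, stratum_names=names, init=init,
                      g_idx=gi, e_idx=ei)
    get = lambda nm: float(fit.sigma[nm][0, 0]) if nm in fit.sigma else 0.0
    # map the fitted parameters onto the full 3-component order
    full_idx = {nm: i for i, (nm, _, _) in enumerate(fit.param_index)}
    asy = np.zeros((3, 3))
    for i, nm_i in enumerate(STRATA):
        for j, nm_j in enumerate(STRATA):
            if nm_i in full_idx and nm_j in full_idx:
                asy[i, j] = fit.asy_cov[full_idx[nm_i], full_idx[nm_j]]
    boundary = [nm for nm in ("genotype", "gxe")
                if nm in fit.sigma and fit.sigma[nm][0, 0] <= fit.floor * 4]
    return VarianceComponents(
        trait=trait,
        sigma_g2=get("genotype"),
        sigma_ge2=get("gxe"),
        sigma_e2=get("residual"),
        loglik=fit.loglik,
        asy_cov=asy,
        method="REML",
        boundary=boundary,
        degenerate=fit.degenerate,
        n_iter=fit.n_iter,
        fit=fit,
    )


def _paired_frame(table: pd.DataFrame, trait1: str, trait2: str) -> pd.DataFrame:
    wide = (
        table[table["trait"].isin([trait1, trait2])]
        .pivot_table(index=KEY, columns="trait", values="value",
                     observed=True)
        .dropna()
        .reset_index()
    )
    if wide.empty or trait1 not in wide or trait2 not in wide:
        raise ValueError(
            f"traits {trait1!r} and {trait2!r} share no (genotype, "
            "environment, replicate) observations")
    return wide


def fit_reml_bivariate(
    table: pd.DataFrame,
    trait1: str,
    trait2: str,
    design: DesignInfo | None = None,
    *,
    init: str = "equal",
) -> CovarianceComponents:
    """Bivariate REML with unstructured 2x2 blocks per stratum.

    Observations are paired by (genotype, environment, replicate); plants
    carrying only one of the two traits are dropped.
    """
    wide = _paired_frame(table, trait1, trait2)
    g_lv, gi = np.unique(wide["genotype"].to_numpy(), return_inverse=True)
    e_lv, ei = np.unique(wide["environment"].to_numpy(), return_inverse=True)
    g, t = len(g_lv), len(e_lv)
    N = len(wide)
    Zg = np.zeros((N, g))
    Zg[np.arange(N), gi] = 1.0
    Zge = np.zeros((N, g * t))
    Zge[np.arange(N), gi * t + ei] = 1.0
    X = np.zeros((N, t))
    X[np.arange(N), ei] = 1.0
    Y = wide[[trait1, trait2]].to_numpy(float)
    fit = fit_mv_reml(Y, X, [Zg, Zge], stratum_names=("genotype", "gxe"),
                      init=init, g_idx=gi, e_idx=ei)

    def vc_of(col: int, other: int) -> VarianceComponents:
        trait = (trait1, trait2)[col]
        idx = {nm: i for i, (nm, a, b) in enumerate(fit.param_index)
               if a == col and b == col}
        asy = np.zeros((3, 3))
        for i, nm_i in enumerate(STRATA):
            for j, nm_j in enumerate(STRATA):
                asy[i, j] = fit.asy_cov[idx[nm_i], idx[nm_j]]
        return VarianceComponents(
            trait=trait,
            sigma_g2=float(fit.sigma["genotype"][col, col]),
            sigma_ge2=float(fit.sigma["gxe"][col, col]),
            sigma_e2=float(fit.sigma["residual"][col, col]),
            loglik=fit.loglik,
            asy_cov=asy,
            method="REML",
            degenerate=fit.degenerate,
            n_iter=fit.n_iter,
        )

    vc1, vc2 = vc_of(0, 1), vc_of(1, 0)
    flags = []
    for nm in STRATA:
        S = fit.sigma[nm]
        bound = np.sqrt(max(S[0, 0] * S[1, 1], 0.0))
        if abs(S[0, 1]) > bound * (1 + 1e-9) and bound > 0:
            flags.append(f"{nm}_cov_exceeds_bound")
        # constrained solution pinned to the PSD boundary (|r| -> 1 or a
        # variance at the floor): identities that assume an interior
        # optimum (e.g. polarization) do not apply
        scale = max(S[0, 0], S[1, 1], fit.floor)
        if np.linalg.eigvalsh(S).min() <= 1e-7 * scale:
            flags.append(f"{nm}_singular")
    return CovarianceComponents(
        trait1=trait1,
        trait2=trait2,
        cov_g=float(fit.sigma["genotype"][0, 1]),
        cov_ge=float(fit.sigma["gxe"][0, 1]),
        cov_e=float(fit.sigma["residual"][0, 1]),
        vc1=vc1,
        vc2=vc2,
        loglik=fit.loglik,
        asy_cov=fit.asy_cov,
        param_index=fit.param_index,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests

def lrt_component(loglik_full: float, loglik_reduced: float,
                  component: str = "genotype", *, tol: float = 1e-6) -> LrtResult:
    """LRT of a single variance component against its boundary null.

    The default reference is the 50:50 mixture of chi2_0 and chi2_1 that is
    correct when the null pins the component to the boundary of the
    parameter space; the naive chi2_1 p-value is reported alongside.
    """
    if loglik_reduced > loglik_full + tol * (abs(loglik_full) + 1.0):
        raise ValueError(
            f"reduced model log-likelihood ({loglik_reduced:.6g}) exceeds the "
            f"full model ({loglik_full:.6g}): optimizer failure")
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    p_naive = float(stats.chi2.sf(stat, df=1))
    p_mix = 1.0 if stat == 0.0 else 0.5 * p_naive
    return LrtResult(component=component, statistic=stat,
                     p_mixture=p_mix, p_naive=p_naive)


def component_lrt(table: pd.DataFrame, trait: str, component: str,
                   *, init: str = "equal") -> LrtResult:
    """Fit full and reduced models and test `component` (genotype or gxe)."""
    if component not in ("genotype", "gxe"):
        raise ValueError("component must be 'genotype' or 'gxe'")
    full = fit_reml_univariate(table, trait, init=init)
    reduced_strata = tuple(s for s in ("genotype", "gxe") if s != component)
    red = fit_reml_univariate(table, trait, include=reduced_strata, init=init)
    return lrt_component(full.loglik, red.loglik, component)
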