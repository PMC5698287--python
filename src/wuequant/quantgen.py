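"""Genetic summary statistics built on variance and covariance components.

* mean-basis broad-sense heritability with a first-order delta-method
  standard error,
* BLUP genotype means for balanced trials (shrinkage toward the grand
  mean, with shrinkage factor identical to the mean-basis heritability),
* phenotypic / genotypic / environmental correlations between trait pairs
  with delta-method standard errors and an optional genotype-deletion
  jackknife cross-check.

The heritability of a genotype mean over t environments and r replicates is

    h2 = sigma_g2 / (sigma_e2/(r t) + sigma_ge2/t + sigma_g2)

which is also the regression of the true genotype effect on the observed
genotype mean, hence the BLUP shrinkage factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import CovarianceComponents, VarianceComponents, validate_balance

__all__ = [
    "HeritabilityEstimate",
    "BlupTable",
    "CorrelationEstimate",
    "heritability_mean_basis",
    "blup_genotype_means",
    "correlations_from_components",
    "genotype_mean_pearson",
    "jackknife_rg",
]


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    se: float
    t: int
    r: int


@dataclass
class BlupTable:
    """Shrunken genotype means: BLUP_i = mu + lambda (ybar_i - mu)."""

    trait: str
    blups: pd.Series          # index genotype, values predicted means
    grand_mean: float
    shrinkage: float
    full_shrinkage: bool = False


@dataclass
class CorrelationEstimate:
    trait1: str
    trait2: str
    r_p: float
    r_g: float
    r_e: float
    se_p: float
    se_g: float
    se_e: float
    basis: str = "individual"          # or "genotype-mean"
    flags: list[str] = field(default_factory=list)


def heritability_mean_basis(vc: VarianceComponents, t: int, r: int) -> HeritabilityEstimate:
    """Broad-sense heritability of a genotype mean, with delta-method SE.

    The SE propagates ``vc.asy_cov`` (covariance of the three component
    estimates) through the gradient of the ratio.
    """
    if t < 1 or r < 1:
        raise ValueError("t and r must be >= 1")
    sg, sge, se_ = vc.sigma_g2, vc.sigma_ge2, vc.sigma_e2
    denom = se_ / (r * t) + sge / t + sg
    if denom <= 0.0:
        raise ValueError("all variance components are zero; h2 undefined")
    h2 = sg / denom
    grad = np.array([
        (denom - sg) / denom ** 2,       # d h2 / d sigma_g2
        -sg / (t * denom ** 2),          # d h2 / d sigma_ge2
        -sg / (r * t * denom ** 2),      # d h2 / d sigma_e2
    ])
    var = float(grad @ vc.asy_cov @ grad)
    return HeritabilityEstimate(trait=vc.trait, h2=float(h2),
                                se=float(np.sqrt(max(var, 0.0))), t=t, r=r)


def blup_genotype_means(table: pd.DataFrame, vc: VarianceComponents,
                        design=None) -> BlupTable:
    """BLUP genotype means for a balanced trial.

    With balanced data the BLUP of genotype i's mean is
    ``mu + lambda (ybar_i - mu)`` with
    ``lambda = sigma_g2 / (sigma_g2 + sigma_ge2/t + sigma_e2/(r t))``,
    i.e. lambda equals the mean-basis heritability.  Unbalanced trials
    should use the mixed-model solutions carried by the REML fit
    (``VarianceComponents.fit.blup``).
    """
    if design is None:
        design = validate_balance(table, vc.trait)
    if not design.balanced:
        raise ValueError(
            "balanced shrinkage formula requires a balanced design; use the "
            "REML fit's mixed-model BLUPs instead")
    t, r = design.t, design.r
    denom = vc.sigma_g2 + vc.sigma_ge2 / t + vc.sigma_e2 / (r * t)
    lam = 0.0 if denom <= 0.0 else vc.sigma_g2 / denom
    df = table[table["trait"] == vc.trait]
    means = df.groupby("genotype", observed=True)["value"].mean()
    mu = float(means.mean())
    blups = mu + lam * (means - mu)
    return BlupTable(trait=vc.trait, blups=blups, grand_mean=mu,
                     shrinkage=float(lam), full_shrinkage=(lam == 0.0))


# ---------------------------------------------------------------------------
# correlations

def _delta_se(cc: CovarianceComponents, grad_by_param: dict[tuple[str, int, int], float]) -> float:
    grad = np.zeros(len(cc.param_index))
    for i, key in enumerate(cc.param_index):
        grad[i] = grad_by_param.get(key, 0.0)
    var = float(grad @ cc.asy_cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def _ratio_grad(c, v1, v2):
    """Gradient of c / sqrt(v1 v2) with respect to (v1, c, v2)."""
    s = np.sqrt(v1 * v2)
    r = c / s
    return {"v1": -r / (2 * v1), "c": 1.0 / s, "v2": -r / (2 * v2)}, r


def correlations_from_components(
    cc: CovarianceComponents,
    t: int = 1,
    r: int = 1,
    basis: str = "individual",
) -> CorrelationEstimate:
    """Partition the correlation of a trait pair into its three components.

    r_g and r_e use the genotypic and residual strata.  The phenotypic
    correlation on the default ``individual`` (plant) basis sums all three
    strata; the ``genotype-mean`` basis down-weights the G x E and residual
    terms by 1/t and 1/(r t).  Standard errors come from the delta method
    through the joint 9-parameter asymptotic covariance of the bivariate
    REML fit.  Out-of-range or undefined values are flagged, never clipped.
    """
    if basis not in ("individual", "genotype-mean"):
        raise ValueError("basis must be 'individual' or 'genotype-mean'")
    flags = list(cc.flags)
    v1 = {"genotype": cc.vc1.sigma_g2, "gxe": cc.vc1.sigma_ge2,
          "residual": cc.vc1.sigma_e2}
    v2 = {"genotype": cc.vc2.sigma_g2, "gxe": cc.vc2.sigma_ge2,
          "residual": cc.vc2.sigma_e2}
    cov = {"genotype": cc.cov_g, "gxe": cc.cov_ge, "residual": cc.cov_e}

    out = {}
    ses = {}
    for label, stratum in (("g", "genotype"), ("e", "residual")):
        if v1[stratum] <= 0.0 or v2[stratum] <= 0.0:
            out[label], ses[label] = np.nan, np.nan
            flags.append(f"r_{label}_undefined")
            continue
        grads, rho = _ratio_grad(cov[stratum], v1[stratum], v2[stratum])
        out[label] = rho
        ses[label] = _delta_se(cc, {
            (stratum, 0, 0): grads["v1"],
            (stratum, 0, 1): grads["c"],
            (stratum, 1, 1): grads["v2"],
        })
        if abs(rho) > 1.0:
            flags.append(f"r_{label}_out_of_range")

    w = {"genotype": 1.0, "gxe": 1.0, "residual": 1.0}
    if basis == "genotype-mean":
        w = {"genotype": 1.0, "gxe": 1.0 / t, "residual": 1.0 / (r * t)}
    V1 = sum(w[s] * v1[s] for s in w)
    V2 = sum(w[s] * v2[s] for s in w)
    C = sum(w[s] * cov[s] for s in w)
    if V1 <= 0.0 or V2 <= 0.0:
        out["p"], ses["p"] = np.nan, np.nan
        flags.append("r_p_undefined")
    else:
        grads, rho = _ratio_grad(C, V1, V2)
        out["p"] = rho
        ses["p"] = _delta_se(cc, {
            **{(s, 0, 0): w[s] * grads["v1"] for s in w},
            **{(s, 0, 1): w[s] * grads["c"] for s in w},
            **{(s, 1, 1): w[s] * grads["v2"] for s in w},
        })
        if abs(rho) > 1.0:
            flags.append("r_p_out_of_range")

    return CorrelationEstimate(
        trait1=cc.trait1, trait2=cc.trait2,
        r_p=float(out["p"]), r_g=float(out["g"]), r_e=float(out["e"]),
        se_p=float(ses["p"]), se_g=float(ses["g"]), se_e=float(ses["e"]),
        basis=basis, flags=flags)


def genotype_mean_pearson(table: pd.DataFrame, trait1: str, trait2: str):
    """Plain Pearson correlation between per-genotype means of two traits."""
    wide = (
        table[table["trait"].isin([trait1, trait2])]
        .groupby(["genotype", "trait"], observed=True)["value"].mean()
        .unstack("trait")
        .dropna()
    )
    if len(wide) < 3:
        raise ValueError("need at least 3 genotypes with both traits")
    x, y = wide[trait1].to_numpy(), wide[trait2].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant trait: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def jackknife_rg(table: pd.DataFrame, trait1: str, trait2: str,
                 *, init: str = "moment") -> tuple[float, float]:
    """Genotype-deletion jackknife estimate and SE of the genotypic correlation.

    A slower, assumption-light cross-check on the delta-method SE of r_g.
    """
    from .varcomp import fit_reml_bivariate

    genos = table["genotype"].unique()
    n = len(genos)
    if n < 3:
        raise ValueError("jackknife needs at least 3 genotypes")
    full = correlations_from_components(
        fit_reml_bivariate(table, trait1, trait2, init=init)).r_g
    loo = np.empty(n)
    for i, gv in enumerate(genos):
        sub = table[table["genotype"] != gv]
        loo[i] = correlations_from_components(
            fit_reml_bivariate(sub, trait1, trait2, init=init)).r_g
    pseudo = n * full - (n - 1) * loo
    est = float(pseudo.mean())
    se = float(np.sqrt(pseudo.var(ddof=1) / n))
    return est, se
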