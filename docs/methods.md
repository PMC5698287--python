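# Methods

## The model

All estimation assumes the two-way mixed model for one trait observed on
plant k of genotype i in environment j:

    y_ijk = mu + E_j + G_i + (GE)_ij + eps_ijk

with the environment effects E_j fixed and

    G_i ~ N(0, sigma_g^2),   (GE)_ij ~ N(0, sigma_ge^2),
    eps_ijk ~ N(0, sigma_e^2),

all mutually independent. "Environment" is deliberately generic: in a
multi-experiment trial it is the combined experiment × water-treatment
label (a convenience mapper `pipeline.map_environments` collapses the two
columns). Treating environment as fixed matches the use of t (number of
environments) as a plain divisor in the heritability of a genotype mean
and is the common choice when environments are few and deliberately
chosen; a random-environment variant would change the heritability
denominator and is not provided.

For a pair of traits the three scalar variances become unstructured 2×2
covariance blocks Sigma_g, Sigma_ge, Sigma_e, giving the stratum
covariances cov_g, cov_ge, cov_e that the correlation partition uses.

## Estimation

**Balanced route (EMS).** On balanced data the two-way ANOVA mean squares
have expectations MS_err = sigma_e^2, MS_GE = sigma_e^2 + r sigma_ge^2,
MS_G = sigma_e^2 + r sigma_ge^2 + r t sigma_g^2, so the method-of-moments
estimators are closed form. Negative solutions are reported raw and
truncated at zero with a flag. The sampling covariance of the EMS
estimators follows from var(MS_s) = 2 lambda_s^2 / df_s with independent
strata. The ANOVA itself is computed from group means in O(N), which is
what lets the generator's law-of-large-numbers checks run at g = 2000.

**General route (REML).** The restricted likelihood of
V = Sigma_g ⊗ Z_g Z_g' + Sigma_ge ⊗ Z_ge Z_ge' + Sigma_e ⊗ I is
maximised by Fisher scoring on the expected information
I_ij = tr(P V_i P V_j)/2, where P is the usual REML projection. Scoring
steps are damped (step halving) when a full step leaves the positive
semi-definite cone or fails to improve the likelihood, and an EM step —
which can never decrease the restricted likelihood — is the fallback.
Two boundary devices keep the iteration honest:

- *variance floor*: stratum variances are kept at or above 1e-12 times
  the phenotypic variance so V never becomes exactly singular;
- *active set*: a variance pinned at the floor whose score is negative is
  frozen and scoring acts on the remaining parameters, which prevents the
  premature "convergence" an unconstrained step would otherwise fake near
  the boundary (this matters for the null distribution of the
  likelihood-ratio test).

When the EM fallback cannot improve the likelihood either (the projection
onto the PSD cone can void its monotonicity guarantee exactly on the
boundary), the point is a constrained optimum and iteration stops.
Convergence is declared when the relative change in restricted
log-likelihood falls below 1e-8 (500 iterations maximum). Start values
are either an equal split of the phenotypic covariance over the three
strata ("equal", the default — deliberately far from the EMS solution so
that agreement between the two routes is informative) or the
balanced-ANOVA estimates ("moment", used by the pipeline and the large
simulation studies purely to save iterations; both reach the same
optimum). The asymptotic covariance of the estimates is the inverse
expected information at convergence (pseudo-inverse on the boundary).

On balanced data with an interior optimum the REML solution coincides
with the EMS solution; this is verified to 1e-6 relative (observed:
machine precision) and is the main dual-route check of the engine.
Likewise the bivariate covariances equal the polarization construction
cov_x = [var_x(T1+T2) − var_x(T1−T2)]/4 computed from two univariate
fits — an identity that presumes an interior optimum, so trials in which
a 2×2 block is pinned to the PSD boundary (flagged `*_singular`) are
excluded from that comparison.

**Likelihood-ratio tests.** A variance component is tested by refitting
without it. Because the null value lies on the boundary of the parameter
space, the default reference distribution is the 50:50 mixture of chi²₀
and chi²₁; the naive chi²₁ p-value is reported alongside since published
analyses do not always state which was used. Empirical size of the
mixture test at nominal 0.05 is 0.043 over 2000 boundary-null replicates
(g=30, t=r=2). The significance of the *fixed* environment effects is a
Wald chi-square on the GLS environment means at the converged fit — an
REML-based LRT across different fixed-effect structures would be invalid.

## Derived statistics

**Heritability.** h² = sigma_g² / (sigma_e²/(r t) + sigma_ge²/t +
sigma_g²) is the broad-sense heritability of a genotype mean over t
environments and r replicates. Its SE is first-order delta method through
the component covariance matrix. The same ratio is the shrinkage factor
of the balanced BLUP of a genotype mean, BLUP_i = mu + h² (ybar_i − mu);
the identity is asserted to 1e-10. The exact SE formula used in the
literature this mirrors is not published; the delta method is the
documented choice here, and a genotype-deletion jackknife
(`quantgen.jackknife_rg`) is available as an assumption-light
cross-check for correlations.

**Correlations.** r_g = cov_g/√(sigma_g1² sigma_g2²) and r_e uses the
residual stratum only (a variant folding G×E covariance into the
"environmental" term is deliberately *not* the default; the residual
stratum is what plant-to-plant covariation within a genotype and
environment measures). The phenotypic correlation defaults to the
individual-plant basis, (cov_g+cov_ge+cov_e)/√(prod of phenotypic
variances); a genotype-mean basis with 1/t and 1/(r t) weights is
available by switch. SEs are delta method through the joint 9-parameter
asymptotic covariance of the bivariate fit. Values outside [−1, 1]
(possible with REML components) are flagged, never clipped. Delta-method
SEs track the empirical spread of the estimates within ~10% at the
default design (500-replicate calibration).

## The synthetic generator

The trait-level generator draws exactly the model above, multivariate
over traits (normality is what the REML analysis assumes; the data it
emulates imply no other distribution). The default calibration emulates
a sunflower RIL water-use trial with 72 lines, two environments and two
replicates:

| trait | mean | h² (t=r=2) | sigma_ge²/sigma_e² |
|---|---|---|---|
| LMF_s (g g⁻¹) | 0.60 | 0.86 | 0.25 |
| LAR_s (cm² g⁻¹) | 143 | 0.74 | 0.25 |
| water use (mL) | 897 | 0.73 | 0.25 |
| leaf area (cm²) | 386 | 0.63 | 0.25 |
| shoot biomass (g) | 2.77 | 0.60 | 1.0 |
| TE_s (g L⁻¹) | 3.03 | 0.52 | 0.25 |
| SLA (cm² g⁻¹) | 237 | 0.36 | 1.0 |

The heritability pins only a ratio of components, so two free choices
close the system, both fixed once and documented: (i) the G×E-to-error
variance ratio is 0.25 for traits whose interaction is typically
non-significant in such trials and 1.0 for the two where it dominates
(shoot biomass, SLA); (ii) the genotypic SD comes from the span of
predicted genotype means via span ≈ 4.8·sd(BLUP) (the expected range of
72 normal draws) and var(BLUP) = h²·sigma_g². Off-diagonal structure is
limited to the calibrated pair: genotypic correlation −0.55 and residual
correlation −0.25 between TE_s and LMF_s. Environment-2 offsets are
plausible water-deficit responses (TE up, water use, leaf area, SLA and
LMF down). Back-substituting the solved components through the h²
formula reproduces the target heritabilities to 1e-9, and 500-replicate
recovery runs return the genotypic correlation to within 0.005 of −0.55.

The raw-measurement layer inverts latent whole-plant traits (TE_wp, the
three mass fractions renormalized to sum to one, SLA, water use) into the
tables a trial actually records: compartment dry masses, leaf area, a
daily pot water-loss series (a deterministic linear watering ramp plus
the soil-evaporation level) and the matching plant-free evaporation-pot
series. Measurement noise is added last; with zero noise, re-deriving
traits reproduces the latent truth to better than 1e-9 (observed 3e-14),
which pins the derivation formulas and the generator to the same
conventions. Latent draws that violate positivity redraw the plant's
residual; more than 1% redraws aborts, so the calibration cannot drift
into a truncated (non-normal) regime silently.

What the generator does *not* emulate — and hence what passing tests do
not establish about real trials: non-normal or heteroscedastic errors,
spatial or temporal structure within a greenhouse, genetic relatedness
among lines (RILs are treated as unrelated levels of a random factor),
selection or attrition of plants, and any growth dynamics (only endpoint
phenotypes and water-use bookkeeping are produced).

## Conventions and degenerate inputs

- Units are fixed internally: masses g, areas cm², water mL; TE converts
  to g L⁻¹ (factor 1000). Petioles always count as stem; the raw record
  has no petiole field so the convention cannot be broken.
- Soil evaporation is averaged per day over the control pots and
  subtracted day by day; negative corrected days are clamped to zero with
  a warning. A corrected total of zero makes TE undefined and is an
  error.
- The wilting index may exceed 1 (plant grew between the two images);
  such values are kept and flagged.
- Transpiration rate is averaged over the recorded days by default; the
  per-day series is available (`average=False`), since protocols differ
  on whether measurement days are analyzed separately.
- Constant data yield a flagged degenerate fit (all components zero),
  not a crash; fewer than two genotypes, disjoint trait pairings,
  duplicate observation keys and non-numeric values are errors that name
  the offending line or key. Missing values are dropped with a warning
  and the balance flag reflects it; ragged replication reports r as the
  minimum cell count.
- The EMS route requires strict balance and says so; the REML route is
  the general path (joint multi-experiment analyses with partially
  overlapping genotype sets are inherently unbalanced and must use it).

## Problem sizes

The validation suite runs the estimators at the scale of the trials the
package targets: 50 balanced trials for the EMS–REML equivalence, 500
replicates at g=72 for heritability/correlation recovery and SE
calibration, 2000 boundary-null replicates for the LRT size, and 20
trials for the polarization identity. The full acceptance run takes
about three minutes on one core; the dense REML engine solves each
(m·N)×(m·N) system directly, which is the right trade-off for trials of
a few hundred plants.

## Known limitations

- Exactly two random strata besides the residual (genotype, G×E); no
  spatial/row-column corrections, no pedigree or marker relationship
  matrices, no narrow-sense heritability.
- Bivariate (not general multivariate) covariance fitting; correlations
  among m > 2 traits are assembled pairwise.
- The balanced BLUP formula is used for genotype means; unbalanced
  trials fall back to the mixed-model solutions carried by the REML fit.
- Delta-method SEs are first-order asymptotic; at small g or near
  boundaries they can misstate the spread (the jackknife cross-check
  exists for exactly this reason).
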