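# wuequant

Quantitative genetics of whole-plant water-use and biomass-allocation
traits in multi-environment plant trials.

Breeding for transpiration efficiency (TE, the dry biomass produced per
litre of water transpired) requires knowing how much of its variation is
genetic, how stable it is across environments, and which cheaper traits
track it. `wuequant` implements the full analysis chain for pot-based
genotype × environment trials of the kind run on recombinant inbred line
(RIL) populations:

- **Trait derivation** from raw per-plant measurements: evaporation-
  corrected plant water use, shoot and whole-plant TE (g L⁻¹), specific
  leaf area (SLA, cm² g⁻¹), leaf/stem/root mass fractions
  (LMF + SMF + RMF = 1), leaf area ratio (LAR = SLA × LMF), daily
  transpiration rate per unit leaf area, and a wilting index.
- **Variance components** for the two-way mixed model
  `y_ijk = μ + E_j + G_i + (GE)_ij + ε_ijk` (environment fixed; genotype,
  interaction and error random), by balanced-ANOVA expected mean squares
  (closed form) and by REML (Fisher scoring with monotone EM fallback;
  handles unbalanced data), with boundary-corrected likelihood-ratio
  tests of σ²g and σ²ge.
- **Broad-sense heritability on a genotype-mean basis**,

  h² = σ²g / ( σ²e/(r·t) + σ²ge/t + σ²g ),

  with a delta-method standard error, and **BLUP genotype means**, whose
  shrinkage factor equals h² on balanced data.
- **Correlation partitioning**: bivariate REML with unstructured 2×2
  stratum blocks splits the association between two traits into
  phenotypic, genotypic and environmental correlations, each with a
  delta-method SE (genotype-deletion jackknife available as a
  cross-check).
- **A calibrated synthetic-data generator** (trait level and raw-
  measurement level) emulating a sunflower RIL water-use trial: 72 lines
  × 2 environments × 2 replicates, realistic trait means and
  heritabilities, and a built-in genotypic correlation of −0.55 between
  TE and leaf mass fraction.

## Worked example

```python
import numpy as np
import wuequant as wq

cfg = wq.default_ril_config(seed=1)          # 72 RILs x 2 environments x 2 reps
table = wq.simulate_trait_table(cfg)
design = wq.validate_balance(table, "TE_s")
vc = wq.fit_reml_univariate(table, "TE_s")
h2 = wq.heritability_mean_basis(vc, design.t, design.r)
lrt = wq.component_lrt(table, "TE_s", "genotype")
cc = wq.fit_reml_bivariate(table, "TE_s", "LMF_s")
corr = wq.correlations_from_components(cc, design.t, design.r)

print(f"design: g={design.g}, t={design.t}, r={design.r}, balanced={design.balanced}")
print(f"variance components (g, gxe, e): {np.round(vc.as_array(), 4)}")
print(f"h2 (mean basis) = {h2.h2:.3f} +/- {h2.se:.3f}")
print(f"LRT genotype: stat={lrt.statistic:.2f}, p(mixture)={lrt.p_mixture:.2g}")
print(f"TE_s vs LMF_s: r_p={corr.r_p:.2f} ({corr.se_p:.2f}), "
      f"r_g={corr.r_g:.2f} ({corr.se_g:.2f}), r_e={corr.r_e:.2f} ({corr.se_e:.2f})")
```

prints

```
design: g=72, t=2, r=2, balanced=True
variance components (g, gxe, e): [0.1135 0.0367 0.2806]
h2 (mean basis) = 0.562 +/- 0.104
LRT genotype: stat=11.76, p(mixture)=0.0003
TE_s vs LMF_s: r_p=-0.31 (0.07), r_g=-0.44 (0.16), r_e=-0.43 (0.07)
```

Read: genotypic differences explain about 56% of the variance of a
genotype's mean TE over this design (the generator was calibrated to
h² = 0.52; one simulated trial lands at 0.562 ± 0.104), the genotype
variance is clearly non-zero (boundary-corrected LRT p ≈ 3 × 10⁻⁴), and
plants and genotypes that allocate more biomass to leaves are less
water-efficient — the estimated genotypic correlation of −0.44 (true
value −0.55) and environmental correlation of −0.43 carry the same sign,
suggesting a physiological rather than purely linkage-driven association.

The same analysis is available from the shell:

```sh
wuequant simulate --seed 1 --out pheno.csv
wuequant run-all --phenotypes pheno.csv --out-dir results/
```

which writes `summary.csv` (per-trait mean, BLUP range, component
p-values, h² ± SE), `components.csv`, `correlations.csv` and a
`run_log.json` with every seed and switch needed to reproduce the bundle
bit for bit. `wuequant derive-traits` turns raw per-plant CSVs (biomass
compartments, leaf area, daily water use, empty-pot evaporation) into the
tidy phenotype table the rest of the pipeline consumes.

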