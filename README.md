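# gblupad — additive–dominance genomic prediction without pedigree

`gblupad` dissects the genetic control of quantitative traits in populations
with **no pedigree information**, the situation faced by breeders of
non-domesticated perennials such as the juçara palm (*Euterpe edulis*): a
stand of genotypes of unknown relatedness, phenotyped over several unbalanced
field seasons and genotyped at thousands of SNPs.  With marker data the
unknown kinship can be *realized* rather than assumed, and the genetic
variance can be split into additive and dominance parts — something a
pedigree-free pedigree-BLUP can never do.

## Models

Three nested mixed models are fitted to the long-format records
(genotype × year), with year as a fixed effect:

| model    | equation                        | kinship                       |
|----------|---------------------------------|-------------------------------|
| BLUP     | y = Xμ + Za + ε                 | A = I (relatedness unknown)   |
| GBLUP-A  | y = Xμ + Zg + ε                 | G (VanRaden)                  |
| GBLUP-AD | y = Xμ + Z₁g + Z₂d + ε          | G and D (Vitezica)            |

with `G = WW′ / Σⱼ 2pⱼ(1−pⱼ)` built from the centered dosages
`W_ij ∈ {2−2pⱼ, 1−2pⱼ, −2pⱼ}` and
`D = SS′ / 4Σⱼ(pⱼ(1−pⱼ))²` from the genotype-class coding
`S_ij ∈ {−2(1−pⱼ)², 2pⱼ(1−pⱼ), −2pⱼ²}`.

Variance components are estimated by REML; from them the package derives

* narrow- and broad-sense heritability `h² = σ²ₐ/σ²_P`, `H² = (σ²ₐ+σ²_d)/σ²_P`;
* the dominance fraction `d² = σ²_d/σ²_P`;
* the additive retention ratio `RL_aa = σ²ₐ(AD)/σ²ₐ(A)` — values well below 1
  mean the additive-only model absorbed dominance variance;
* theoretical accuracy `r = √(1 − PEV/σ²_g)` from the mixed-model-equation
  prediction error variance;
* AIC/BIC and a boundary-corrected (½χ²₀+½χ²₁) likelihood-ratio test for the
  dominance component;
* predictive ability `r_{y,û}` by 5-fold cross-validation over genotypes.

A synthetic-data generator with known σ²ₐ, σ²_d, σ²ₑ (marker effects drawn on
the same W/S codings the kernels use, so the configured variances are the
exact REML estimands) makes every stage testable end to end.

## Worked example

```python
import numpy as np
from gblupad import (SimulationConfig, simulate_dataset, qc_filter,
                     additive_kernel, dominance_kernel, fit_dominance_pair,
                     lrt_dominance, cross_validate)

cfg = SimulationConfig(n_individuals=275, n_markers=2000,
                       sigma2_a=0.4, sigma2_d=0.2, sigma2_e=0.4, seed=7)
ds = simulate_dataset(cfg)                       # 3 seasons, 825 records
panel, report = qc_filter(ds.genotypes)          # call rate >= 90%, MAF >= 5%
G, D = additive_kernel(panel), dominance_kernel(panel)
res_a, res_ad = fit_dominance_pair(ds.phenotypes, G, D)
print(res_ad.summary())
print("LRT (dominance):", lrt_dominance(res_a, res_ad))
print("CV r:", cross_validate(ds.phenotypes, [G, D], k=5, seed=1).mean_r)
```

prints (abridged):

```
GBLUP-AD REML fit
  records: 825  individuals: 275  years: [2018, 2019, 2021]
  converged: True  iterations: 13
  variance components:
    sigma2[additive] = 0.320313
    sigma2[dominance] = 0.247866
    sigma2[residual] = 0.371315
  logLik = -999.3765   AIC = 2004.7529   BIC = 2018.8882
  mean PEV = 0.100751   accuracy r = 0.9070
LRT (dominance): (6.311206018938947, 0.005998860014510761)
CV r: 0.3131723216868632
```

The fit recovers the generating components (0.4, 0.2, 0.4) within sampling
error, the likelihood-ratio test detects the simulated dominance
(p ≈ 0.006 under the boundary mixture), and the cross-validated predictive
ability (0.31) is far above the exact 0 that the identity-kernel BLUP scores
for untested genotypes.

The same analysis runs from the shell over CSV/VCF inputs:

```bash
gblupad simulate --study-trait FWB --n-markers 2000 --seed 7 --out-prefix fwb
gblupad fit fwb_genotypes.csv fwb_phenotypes.csv --model GBLUP-AD
gblupad all config.yaml       # QC -> kernels -> fits -> LRT -> CV reports
```

`gblupad.study` bundles the reference population that the defaults emulate —
275 juçara palm genotypes, 12 fruit-production traits, 2018–2021 seasons,
44,457 SNPs pre-QC / 8,112 post-QC — including its published per-year trait
summaries, variance components and fit criteria.

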