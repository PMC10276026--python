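# Methods

## The statistical model

All three models are special cases of the multi-kernel linear mixed model

    y = Xβ + Σ_k Z u_k + ε,    u_k ~ N(0, K_k σ²_k),    ε ~ N(0, I σ²_e)

fitted to long-format records, one per (genotype, year).  `X` is the year
incidence matrix in **cell-means form** — one column per observed year, no
intercept — so β holds one mean per year.  `Z` is the record→individual
incidence shared by every genetic term; repeated records of one individual
therefore share a single genetic effect per term, and there is no separate
permanent-environment term.  The kernels are

* identity `I` for the no-pedigree baseline BLUP (`a ~ N(0, I σ²_a)`):
  with relatedness unknown, the pedigree matrix degenerates to the identity;
* the additive genomic kernel `G = WW′ / Σⱼ 2pⱼqⱼ` (centered dosages
  `W = dosage − 2pⱼ`);
* the dominance genomic kernel `D = SS′ / 4Σⱼ(pⱼqⱼ)²` with the
  genotype-class coding `S ∈ {−2pⱼ², 2pⱼqⱼ, −2qⱼ²}` for dosages {0, 1, 2}.

Both kernels use allele frequencies recomputed on the post-QC panel, have
expected diagonal 1 under Hardy–Weinberg proportions, and are elementwise
invariant to which allele the dosage counts (property-tested).  Dosage
orientation: the dosage-2 homozygote receives the W code `2−2p` and the S
code `−2q²`, keeping the two codings consistent.

### Missing genotypes

QC keeps markers with call rate ≥ 0.90 and MAF ≥ 0.05 (both inclusive —
ties resolved toward retention).  Remaining missing dosages are
mean-imputed (`2pⱼ`) **before building W**, which leaves W's column means at
exactly zero.  The S coding is class-based with no meaningful linear
interpolation, so S is built from the pre-imputation integer matrix with
missing cells coded 0 (the HWE-expected code is mean-zero); the count is
logged.  Post-QC missingness is at most 10% per marker by construction, so
the choice is numerically immaterial; it is nonetheless isolated in
`build_S` and easy to change.

## REML estimation

Variance components maximize the restricted log-likelihood

    l(σ²) = −½ [ log|V| + log|X′V⁻¹X| + y′Py + (n−p) log 2π ],
    V = Σ_k σ²_k Z K_k Z′ + σ²_e I.

The constant convention (the `(n−p) log 2π` term, no `|X′X|` adjustment) is
fixed so that likelihood *differences* — the LRT statistic and information
criteria — are convention-free.

**Optimization.**  Bounded quasi-Newton (L-BFGS-B) on θ = log σ² with the
analytic gradient ∂l/∂σ²_k = −½[tr(P V_k) − y′P V_k P y]; bounds
[10⁻⁸·var(y), 10³·var(y)] keep the components positive while letting them
reach an effective zero.  Convergence uses the optimizer's tight ftol/gtol
(1e−13 / 1e−8); on failure a safeguarded fixed-point iteration
(σ²_k ← σ²_k·√(y′PV_kPy / tr(PV_k)), whose fixed points are exactly the
stationary points) polishes the estimate, and the `converged` flag is
reported honestly.  Components ending within a factor 2 of the lower bound
are flagged `boundary` (a genuinely dominance-free trait lands there).
For nested model comparison `fit_dominance_pair` additionally warm-starts
the additive-dominance fit from the additive-only optimum, taking the best
of the two starts, which keeps LL(AD) ≥ LL(A) for the LRT.

**Computation.**  Because every genetic term shares Z and the residual is
i.i.d., V = σ²_e I + Z M Z′ with M = Σ_k σ²_k K_k of dimension
n(phenotyped individuals).  Factorizing M = AqAq′ (eigendecomposition,
negative round-off eigenvalues clipped at zero) reduces every V-solve,
log-determinant, gradient trace, BLUP and PEV to operations on the
n×n matrix B = σ²_e I + Aq′Z′Z·Aq — cost O(n³) per likelihood evaluation
instead of O(N³) in the record count N.  The implementation is tested to
1e−8 against an independent dense-formula evaluation and to float precision
against Henderson's K⁻¹-form mixed-model equations.  If a factorization
fails, a single 1e−6 relative diagonal jitter is retried *inside the solver
only*; reported matrices are never altered.

**Solutions and PEV.**  At the optimum, û_k = σ²_k K_k Z′Py (the BLUP, also
valid for individuals without records, which is how cross-validation
predicts), and the prediction error variance is the diagonal of
σ²_k K_k − σ²_k K_k Z′PZ K_k σ²_k — the same quantity as the inverse-MME
diagonal block, without inverting possibly singular kernels.  For the
additive-dominance model the genetic prediction is û = ĝ + d̂ and its PEV is
that of the *sum*, including the error cross-covariance of the two terms
(verified against the joint inverse coefficient matrix).  The scalar PEV
reported per trait×model is the **mean over individuals** of the
genetic-term PEV; the aggregation is a documented choice (mean, not median)
since no canonical definition exists for a single-number summary.

## Derived parameters and model comparison

With σ²_P = σ²_a + σ²_d + σ²_e: h² = σ²_a/σ²_P, H² = (σ²_a+σ²_d)/σ²_P,
d² = σ²_d/σ²_P (so h² + d² = H² identically), RL_aa = σ²_a(AD)/σ²_a(A), and
accuracy r = √(1 − PEV/σ²_g) clipped at 0 if PEV exceeds σ²_g.  σ²_g in the
accuracy formula is the *model's total genetic variance*: σ²_a for
single-kernel models, σ²_a + σ²_d for the additive-dominance model — the
convention under which the package reproduces the reference population's
accuracy table from its components.

**Information criteria.**  AIC = 2k − 2·logLik and
BIC = −2·logLik + k·log(v) with v = n_records − rank(X) residual degrees of
freedom and — deliberately non-standard — **k = the number of fixed-effect
(year) parameters only**, variance components not counted.  This is the
counting convention under which the reference AIC table is reproducible
from its log-likelihoods (k = 4 for the four-season bunch-count trait, 3
elsewhere); it is prominently documented because most software counts
variance parameters too.  Since k is equal across the models compared for a
given trait, rankings are unaffected.

**Dominance LRT.**  2(LL_AD − LL_A), clipped at 0.  Under H₀: σ²_d = 0 the
parameter sits on the boundary, so p-values use the ½χ²₀ + ½χ²₁ mixture
(p = 0.5 at statistic 0).  Simulation at n = 300 (200 null replicates) puts
the empirical size at the nominal 5% (measured 5.0%, with 47% of statistics
exactly zero, close to the asymptotic half).

## Cross-validation

Folds partition *genotypes* (all years masked together; a 275-genotype
population in 5 folds gives the 220/55 train/validation split), so no
record of a validation genotype can inform its own prediction — the
training table is a strict subset of the records, byte-identical to direct
subsetting (tested).  Variance components are refit per fold by default
(configurable to reuse full-data estimates).  Validation genotypes remain
in the kernel with no records and are predicted through it; predictive
ability is the per-fold Pearson correlation between those predictions
(â, ĝ, or ĝ+d̂) and each validation genotype's across-year phenotype mean,
averaged over folds with SE = sd/√k.  With the identity kernel no
information flows to unphenotyped genotypes — predictions are constant —
and such folds score r = 0 by convention rather than NaN, making "BLUP
cannot rank untested genotypes" an exact, testable statement.

## The synthetic-data generator

The generator emulates the reference population: unlinked biallelic SNPs
with frequencies uniform on [0.05, 0.5], Binomial(2, pⱼ) dosages
(Hardy–Weinberg), MCAR missingness, and unbalanced multi-year records
(default three seasons; the study's fourth season exists only for the
bunch-count trait, and `gblupad.study` reproduces that pattern with the
published per-year means as fixed year effects).  Marker effects are drawn
i.i.d. with Var(αⱼ) = σ²_a/Σ2pⱼqⱼ and Var(δⱼ) = σ²_d/4Σ(pⱼqⱼ)² **on the
same W/S codings used by the kernels**, so g = Wα and d = Sδ satisfy
Var(g) → σ²_a, Var(d) → σ²_d and the configured variances are the exact
REML estimands — parameter recovery is then a well-posed acceptance test.
Defaults for the generic config are σ²_a = 0.4, σ²_d = 0.2, σ²_e = 0.4
(h² = 0.4, d² = 0.2, in the range of the reference traits).

What the generator deliberately omits — linkage disequilibrium, population
structure, inbreeding, selection, genotype-by-year interaction — bounds
what passing tests show: they validate the estimation machinery under the
model's own assumptions, not robustness to real-genome LD or stratification.

One emergent property deserves emphasis: the "additive inflation" effect
(σ̂²_a larger in the additive-only model than in the additive-dominance
model) **requires repeated records per individual**.  With single records
the residual and dominance structures are confounded enough that the
dominance variance drains into σ̂²_e and the inflation is absent (measured
12/30 replicates, mean ≈ 0 at n = 500, m = 2000); with the default
three-season records the residual is identified from within-individual
replication, the additive kernel is the only term left that can absorb the
between-individual dominance signal, and inflation holds in 30/30
replicates (mean +0.22 on a true σ²_a = 0.4).  The multi-year design is
therefore not a nuisance detail of the emulated study but the condition
that makes its central observation reproducible.

## Problem sizes used in validation

Chosen as the package's own verification scale: parameter recovery and
inflation at n = 500 individuals × m = 2,000 markers × 3 seasons ×
30 replicates; LRT size at n = 300 × m = 1,000 × 200 null replicates;
CV comparisons at n = 150 × m = 300 × 15 replicates (h² = d² = 0.25 for the
high-dominance condition) plus exactness checks at small n.  All stochastic
routines take explicit seeds (child seeds spawned from one root via
`numpy.random.SeedSequence`), and the pipeline writes a manifest (without
timestamps) so a rerun with the same config is byte-identical.

## Known limitations

* Single-trait models only; no genetic correlations, no multi-trait LRT.
* No genotype-by-environment interaction or spatial terms.
* The dominance coding assumes integer genotype classes; heavily imputed
  panels degrade D more than G.
* REML standard errors of the variance components (inverse average
  information) are not reported, matching the scope of the reference
  tables.
* The LRT mixture is asymptotic; at very small n the test is conservative.
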