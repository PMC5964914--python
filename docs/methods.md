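# Methods

This document describes the statistical models implemented in `hornpred`,
the design of the synthetic study generator, the defaults and the reasoning
behind them, and the numerical choices in the mixed-model core.

## 1. Traits and data model

Horn status is scored in four classes — polled, knobs, scurs, horned — and
analysed through two binary traits:

- **P/NP** (`pnp`): polled (1) vs. everything else (0);
- **H/NH** (`hnh`): horned (1) vs. everything else (0).

Knobs and scurs are intermediate expressions and are always pooled in the
analyses. Sex takes two labels, `female` and `wether` (castrated male);
castration suppresses horn growth, which is one reason male penetrance is
incomplete. Genotypes are 0/1/2 dosages of the polled-associated allele at
each marker; the causal locus is a chromosome-10 insertion represented as a
biallelic marker. Phase, when present, is carried as two haplotype
matrices. Pedigrees are validated for cycles, unknown parents and sex
consistency; marker QC filters on call rate, MAF, Hardy–Weinberg
equilibrium, and autosomal position.

## 2. Synthetic study generator

`simulate_study(SimConfig(seed=...))` produces a complete study: pedigree,
phased genotypes, and phenotypes. **The defaults are the study conditions**
— a half-sib progeny-test design of 182 sires with 1–51 offspring each
(≈ 4 600 phenotyped animals), dams carrying 1.5 offspring on average, a
female fraction of 0.61, and a causal allele frequency of 0.295.

### 2.1 Founder haplotypes and LD

The core chromosome-10 segment (41 SNPs in 600 kb around the insertion)
needs realistic LD between the causal locus and its two designated tag SNPs
(target r² = 0.985 each). Founder haplotypes follow a **mosaic lineage
model**: each haplotype belongs to one of two ancestral lineages at the
causal site, and lineage identity is propagated marker-to-marker by a Markov
chain with a per-interval *retention* probability; at each switch the
lineage is redrawn from its marginal frequency. Allele frequencies at
flanking markers are conditioned on lineage so that retention maps directly
onto r².

Retentions are **calibrated**: the r² between the causal locus and a marker
k intervals away is the product of the retentions on the connecting path, so
each tag's target fixes that product; segments between consecutive tags get
the implied per-interval value, and markers beyond the outermost tags decay
at a background retention of 0.90. Targets are checked against the
**Hill–Robertson bound** r²max attainable for two loci with the given
allele frequencies; an unreachable target is an error, not a silent clamp.

### 2.2 Gene dropping and phenotypes

Non-founder haplotypes are generated by gene dropping with recombination;
each meiosis picks crossover points and copies parental haplotype segments,
so phase is exact by construction. Phenotypes are drawn from a **sex ×
genotype penetrance table** over (polled, knobs+scurs, horned). The default
table is the observed class fraction in a large Merino dataset:

| sex    | g | P(polled) | P(horned) |
|--------|---|-----------|-----------|
| female | 0 | 0.141     | 0.066     |
| female | 1 | 0.770     | 0.006     |
| female | 2 | 0.847     | 0.006     |
| wether | 0 | 0.041     | 0.674     |
| wether | 1 | 0.531     | 0.012     |
| wether | 2 | 0.782     | 0.000     |

with g the dosage of the polled-associated allele. A polygenic liability
component (default σ²ₐ = 0.2 on the logit scale) is dropped through the
pedigree (founders N(0, σ²ₐ), offspring mid-parent plus Mendelian sampling
N(0, σ²ₐ/2)) and shifts the class logits, creating the family-correlated
residual variation that pedigree/genomic models then recover.

**Scope and limits.** The generator reproduces what the downstream methods
consume: family structure, tag–causal LD, sex-dependent penetrance, and a
polygenic signal. It does not model selection, assortative mating,
genotyping batch effects, or LD *between* background markers (the 120
background SNPs on five other chromosomes are independent loci, present so
genome-wide relationship matrices are estimable). Inbreeding arises only if
the random pedigree happens to create it.

## 3. Relationship matrices

- **Pedigree NRM (A)** — tabular method in topological order:
  A(x,x) = 1 + ½A(sire, dam), A(x,y) = ½[A(y, sire) + A(y, dam)].
- **Additive GRM (G)** — VanRaden's first method: W = M − 2p (M the dosage
  matrix, p observed allele frequencies), G = WW′/c with
  c = 2Σ pⱼ(1−pⱼ). Missing genotypes are mean-imputed; monomorphic
  markers are excluded (and all-monomorphic input is an error).
- **Dominance matrix (D)** — classical parameterisation with heterozygosity
  codes −2p², 2p(1−p), −2(1−p)² for dosages 0/1/2 and denominator
  Σ(2pⱼ(1−pⱼ))². Columns are centred under HWE, making D orthogonal to G
  in expectation.

A small ridge (1e−6 on the diagonal) stabilises inversion wherever a
relationship matrix is factorised.

## 4. Mixed-model core

The model is y = Xβ + Σᵢ Zᵢuᵢ + e with uᵢ ~ N(0, σ²ᵢKᵢ) (Kᵢ = I for
marker-design terms) and e ~ N(0, σ²ₑI).

- **Henderson's equations** (`solve_mme`) give β̂ and BLUPs at fixed
  variances; confounded fixed columns are reported by name.
- **ML/REML** (`fit_variance_components`) maximises the (restricted)
  likelihood over log σ² with L-BFGS-B, falling back to Nelder–Mead on a
  bound-clipped objective. Two likelihood paths:
  - *Rotated path*: with at most one animal-dimensional K, the model is
    rotated into K's eigenbasis. K is eigendecomposed **blockwise** over the
    connected components of its sparsity pattern — under a half-sib pedigree
    the cost scales with the largest family, not with n. Remaining low-rank
    design terms are absorbed by the Woodbury identity, so a GBLUP fit whose
    G derives from ~160 markers costs seconds, not minutes, and is exact.
  - *Dense path*: several dense K's fall back to a Cholesky of the full V.
- Variance components live on the log scale, bounded in [1e−8, 1e8] × the
  phenotypic variance; estimates at the lower bound are flagged as
  **boundary** (a null component) rather than reported as spuriously small
  positive values.
- **AIC** = −2·loglik(ML) + 2·(#fixed + #variance parameters) compares
  models; REML likelihoods are only comparable across identical fixed
  structures, and mixing them is an error. Ties go to the simpler model.
- **Dempster–Lerner transform** maps observed-scale h² of a binary trait to
  the liability scale, h²_liab = h²_obs · K(1−K)/φ(t)², with K the
  prevalence and t the threshold; at K = 0.5 the multiplier is exactly π/2.

### Numerical guards

The Woodbury quadratic form can cancel catastrophically at extreme variance
ratios; a materially negative value raises and is treated as an infeasible
point (objective 1e30), and small negative values are clamped to zero. The
derivative-free fallback optimises a clipped objective with a quadratic
penalty outside the bounds, so it cannot escape to degenerate solutions.

## 5. Association and mode of inheritance

`gwas_scan` tests each marker by the added sum of squares of its dosage in a
linear model on the binary trait with optional covariates (sex by default in
the CLI); monomorphic or confounded markers are flagged unusable, never
given a fabricated p-value. Ties among top markers break toward the marker
nearest a stated position.

Five nested **mode-of-inheritance models** describe the causal-marker
effect: (1) additive α; (2) α + heterozygosity effect δ; (3) sex-specific
α; (4) α + sex-specific δ; (5) sex-specific α and δ. Sex is always a fixed
main effect (hierarchy principle); marker effects are random, one variance
per term, fitted by ML and compared by AIC. A sex with no heterozygotes
makes its per-sex dominance term unidentifiable and is an error, reported in
the selection table.

The **degree of dominance** is computed from genotype-class means per sex:
a = (m₂−m₀)/2 after orienting so m₂ ≥ m₀, d = m₁ − (m₀+m₂)/2; |d/a| = 1 is
complete dominance. A sex with an empty genotype class is reported
unavailable, not extrapolated.

## 6. Haplotypes

Haplotype alleles over k markers are read directly off phase as bit-strings
in map order. Alleles under 2% frequency are pooled into a residual class
(idempotently; an all-rare set is an error). The copy-count matrix (rows
sum to 2) enters prediction as a random-effect design with one shared
variance; a single-class design is rejected as confounded with the
intercept.

## 7. Prediction and validation

**Marker models** (`predict_marker_model`) fit intercept + sex plus the
marker (or haplotype) random terms on the training animals, optionally joint
with a polygenic term (A or G restricted to training). Validation
predictions add the fixed part, the marker solutions applied to validation
designs, and the polygenic BLUP obtained from the covariance of validation
with training animals: u_val = K_vt (K_tt + εI)⁻¹ û_train. Validation
animals unrelated to training get exactly zero. The causal-insertion
predictor supports a symmetric genotyping-error rate emulating imputation
error.

**GBLUP** (`gblup_predict`) estimates variances on training animals (via
the low-rank marker-design path when codings are supplied) and projects to
validation by either of two algebraically identical routes:

- *covariance*: g_val = G_vt (G_tt + εI)⁻¹ ĝ_train;
- *backsolve*: per-marker effects α̂ = (1/c) W′ (G + εI)⁻¹ ĝ applied to the
  validation codings.

Both are implemented and agree to machine precision when G is built from
the same codings; the same holds for the dominance term.

**Validation designs**: repeated k-fold CV (default 5 × 5) over animals;
**within-family** splits (each big half-sib family contributes half its
offspring to training, odd counts toward training); **across-family**
splits (families train or test as whole units, so no sire spans the
divide). Big families are sires with *more than* 13 phenotyped offspring.
**Accuracy** is the Pearson correlation between prediction and the observed
binary trait, per sex; cells with fewer than three pairs or zero variance
are NaN (logged), never silently zero. Reports carry per-fold accuracies
with means and SE = sd/√(#folds).

Training fits never see validation phenotypes: censoring them leaves every
prediction bit-identical, and this is asserted in the test suite.
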