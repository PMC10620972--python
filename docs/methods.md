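# Methods

## Model

`fblmm` fits a Bayesian linear mixed model for quantitative phenotypes
measured in family-based sequencing studies. For n individuals with
centred outcome Y,

    Y = X Γ β + Σ_m r_m g_m + g_f + e_f + ε,        ε ~ N(0, I σ_ε²)

with four kinds of predictors:

- **Isolated common-variant effects** X Γ β. X holds the common-variant
  dosages (and, if supplied, covariates); Γ = diag(γ) with
  γ_j ~ Bernoulli(θ₀) and β_j ~ N(0, σ_β²) form a Bernoulli–Gaussian
  spike-and-slab that selects individually predictive markers without
  under-estimating the posterior variance of β.
- **Region effects** g_m ~ N(0, K_m σ_m²), one per genomic region (gene,
  pathway, …), with region-selection indicators r_m ~ Bernoulli(℘). The
  region kernel K_m = G_m W_m G_mᵀ / p_m measures weighted genetic
  similarity over the p_m region variants, and the weights W_m up-weight
  rare variants (see below), letting a region's common and rare variants
  contribute jointly.
- **Kinship surrogate** g_f ~ N(0, K_gf σ_gf²), where K_gf is the
  expected additive relationship implied by the pedigree (2·kinship;
  diagonal 1 for non-inbred individuals, MZ twins related 1). It stands
  in for unmeasured genetic factors, whose effects aggregate along
  genetic relatedness.
- **Shared-environment surrogate** e_f ~ N(0, K_ef σ_ef²), where K_ef is
  block diagonal with a block of ones per family. It stands in for
  unmeasured environmental exposures shared within a household.

All variance components get IG(0.1, 0.1) priors; θ₀ = ℘ = 0.1 and
σ_β² = 1 by default (σ_β² is fixed, not learned). Every kernel K is
reparameterised through its truncated eigendecomposition as a design
matrix Z = Q Λ^{1/2} with Z Zᵀ = K and diagonal Gram ZᵀZ = Λ, so each
random effect becomes an ordinary Gaussian coefficient vector U with
K-effect = Z U.

## Variant weights

For minor allele frequency f_j ∈ (0, 0.5]:

- `uniform`: w_j = 1 — the infinitesimal model over common variants;
- `wss`: w_j = 1/√(f_j (1 − f_j)) — weighted-sum-statistic weights, the
  default for analysis;
- `beta`: w_j = dbeta(f_j; 1, 25)², with an unsquared option.

Both non-uniform schemes diverge as f_j → 0, so monomorphic variants are
excluded before weighting, and MAF fed to the weight function can be
floored at 1/(2n). MAF can be computed over all samples or founders only
(the default in pipelines with a pedigree, since large families inflate
allele frequencies); region kernels built inside `fit_study` use
training-sample MAF. Whether the weights enter once (diag(w)) or squared
is a genuine ambiguity in the literature; this package applies them once
in K_m, with the beta scheme pre-squared, matching how the beta form is
usually printed.

## Inference

The posterior over ξ = (β, γ, {U_m, r_m}, U_gf, U_ef, variances) is
approximated by the fully factorised mean-field family of the model
description, optimised by coordinate-ascent variational inference
(CAVI). Each factor update is the exact conditional-conjugate solution —
Gaussian factors solve ridge-type normal equations against the expected
residual (using E[Γ] = diag(ψ), E[r_m] = φ_m, E[1/σ²] from the IG
factors, and the diagonal ZᵀZ); Bernoulli factors add the expected
log-likelihood gain of inclusion to the prior log-odds; IG factors add
half the effective dimension to the shape and half the expected sum of
squares to the rate. Exactness of every update gives the CAVI guarantee
that the evidence lower bound (ELBO) never decreases, which the test
suite checks on batteries of random models, alongside two closed-form
oracles: the generalized-ridge/GLS limit (all inclusion probabilities
clamped to 1, variances fixed) and exact enumeration over all (γ, r)
configurations on a two-variant, one-region toy.

Update order is fixed and deterministic: q(β), each q(γ_j) in index
order, each (q(U_m), q(r_m)) pair in region order, q(U_gf), q(U_ef),
then all IG factors. Convergence is declared when the relative ELBO
change drops below 1e-5 (default; max 1000 sweeps).

**Two-start rule.** The kinship and shared-environment surrogates
overlap: both induce positive within-family covariance, and K_gf's unit
diagonal additionally overlaps the residual. From the default
initialisation (ψ = θ₀, φ = ℘, zero means, prior-value IG factors with
the residual rate moment-matched to var(Y)), coordinate ascent can
settle in a local optimum in which the kinship term absorbs variance
that belongs to the shared environment; on data simulated with a pure
family-environment covariance the two fixed points differ by ~180 nats
of ELBO in favour of the correct attribution. `fit()` therefore runs two
deterministic starts — the default, and one with the kinship variance
factor initialised at 100× precision so the environment block gets first
claim on family covariance — and keeps the run with the higher final
ELBO. When the truth is kinship-driven the two starts land within a few
nats of each other and either attribution predicts essentially
identically, so the rule is safe in both regimes.

Numerical floors: IG rates ≥ 1e-12; ψ, φ clipped to [1e-12, 1 − 1e-12]
inside logs; eigenvalues below 1e-8·λ_max truncated so every Z has full
column rank. Y is centred internally (no explicit intercept; the mean is
restored at prediction), X columns are centred at training means. If p
exceeds a configurable cap (default 5000) the joint Gaussian q(β) falls
back to blockwise updates with a warning; the intended workflow for
large p is the marginal pre-screen.

## Prediction

For new individuals, each component contributes its Gaussian-process
conditional mean under the trained variational posterior (no refit):

- regions: ĝ*_m = φ_m K*_m Q_m Λ_m^{-1/2} M_m with the train–test
  cross-kernel K*_m = A_new diag(w) A_trainᵀ / p_m computed under the
  training transforms (training-mean imputation and centring). Scaling
  by φ_m is Bayesian model averaging, E_q[r_m U_m], not a hard
  threshold; fixed effects likewise use ψ-weighted means.
- kinship: ĝ_f* = K*_gf Q_gf Λ_gf^{-1/2} M_gf, with K*_gf the
  expected-relatedness rows between new and training individuals
  computed on the merged pedigree;
- environment: a member of training family F receives F's common fitted
  environmental effect; both familial terms are exactly zero for
  subjects unrelated to every training family, so prediction degrades
  gracefully to genotype-only.

Variants present in training but missing from a request are imputed at
the training mean (zero contribution after centring); unseen variants
are dropped and reported.

## Synthetic studies

The simulator replaces real founder panels with Hardy–Weinberg draws:
each variant receives a target MAF from a mixture spectrum (by default
30% "rare" ~ U(0.001, 0.01), the rest ~ U(0.05, 0.5)) and founder
dosages are Binomial(2, MAF); realized-monomorphic columns are redrawn
up to ten times, then dropped. Pedigrees are assembled from named blocks
(half-sib 5-member, nuclear with 2 or 4 offspring, trio, DZ/MZ twin,
and four minimal three-generation structures: avuncular, double-cousin,
grandparent, sibling). Genotypes descend by gene dropping — each
offspring inherits one uniformly random allele per parent, independently
per locus (no linkage or recombination map; phenotype models use
unlinked regions, so none is needed). MZ co-twins share one transmitted
genome. Pool rows are assigned to pedigree founders without replacement
while the pool lasts, with replacement after.

Three phenotype models:

- **env-only**: Y = α + ε with family effects α ~ N(0, σ_a²); equals
  Y ~ N(0, K σ_a² + I σ²) with K the family block matrix. The
  env_fraction knob is the intraclass correlation σ_a²/(σ_a² + σ²).
  Drawn at theoretical scale (no rescaling).
- **genetic-only**: Y = Σ₃ g_m + ε over three causal regions with
  g_m ~ N(0, K_m) under a configurable causal weight scheme; one region
  is chosen at random as unmeasured and its variants withheld from the
  exported genotypes. Components are rescaled to hit the target
  partition exactly in-sample: total heritability h (default 0.6), a
  fraction of it (default 0.5) on the unmeasured gene.
- **combined** (and the S1–S3 presets): Y = α + Σ₃ g_m + ε with one
  unmeasured region. In the default equal-contribution mode the
  environment share equals the total genetic share, split evenly over
  the three regions. The S presets fix share vectors
  (env, measured, measured, unmeasured) of the explained variance v:
  S1 = (0, ¼, ¼, ½)·v, S2 = (½, ⅛, ⅛, ¼)·v, S3 = (⅙, 1/12, 1/12, ⅔)·v,
  chosen as simple fractions satisfying each model's defining
  inequality (S1: unmeasured = measured sum; S2: environment dominates
  measured genetics; S3: unmeasured dominates everything else).

Ground-truth per-individual components are stored and sum exactly to Y.
What the generator does **not** emulate: linkage disequilibrium,
ascertainment of families, genotyping error, non-additive effects,
binary traits. Passing tests therefore demonstrate correctness of the
machinery and the design-information mechanism under the assumed
generative models, not performance on real cohorts.

## Evaluation pipeline

`fit_study` builds region kernels from the study's region map (WSS
weights by default), uses common variants (MAF ≥ 0.05) *outside* the
regions as the fixed-effect block — region membership and X are kept
disjoint so a variant's effect is not modelled twice — and restricts the
familial kernels to the training samples (kinship is computed on the
full pedigree first, so relatedness through unsampled ancestors is
kept). The optional marginal pre-screen fits the null variance
components σ_g² K_gf + σ_ε² I once by maximum likelihood (profiled
eigen-rotation), whitens, and keeps variants with single-marker
two-sided p ≤ 0.1; with K_gf = I it reduces exactly to OLS.

Train/test splits are uniformly random at the individual level (20%
test by default, matching the usual protocol) or at the whole-family
level for out-of-family evaluation. Metrics are test-set Pearson r and
RMSE, aggregated as medians and quartiles over replicates; replicate k
derives its seed as base + k. The comparison baseline is a genotype-only
gBLUP: a single overall GRM, ML variance components, BLUP prediction —
deliberately blind to the pedigree, so the gap to the full model
isolates the value of the family-design surrogates.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at reduced
scale chosen to exercise every code path while keeping runs quick:
40–80 variants in regions of 6–10, founder pools of 60–500, and 20–1000
families depending on the check (e.g. variance-component recovery uses
1000 nuclear families of 4, n = 4000; the benchmark uses 100 families,
n = 400, 20 replicates per setting). The full two-generation design
(30 half-sib + 177 nuclear-2 + 197 nuclear-4 pedigrees, 2040
individuals) is instantiated exactly for the count checks and is the
default `fig2` preset at full scale.

## Known limitations

- The g_f / e_f split is only weakly identified when family structure is
  shallow (e.g. only MZ twin pairs, where kinship and environment blocks
  coincide up to the diagonal); predictions are robust to the split, but
  the individual variance fractions are not interpretable there.
- Mean-field underestimates posterior variances of the selected effects;
  the package reports point predictions only.
- The q(β) factor is a single joint Gaussian; beyond the cap it switches
  to blockwise updates, which weakens the treatment of strongly
  correlated variants. Pre-screening is the intended control of p.
- The marginal screen estimates null variance components once (not per
  variant), the standard computational shortcut.
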