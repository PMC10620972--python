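# fblmm

Family-based Bayesian linear mixed models for genomic risk prediction.

Family designs (twin studies, nuclear and multi-generation pedigrees)
carry information that population-based prediction methods throw away:
relatives share unmeasured genetic factors in proportion to their
kinship, and household members share unmeasured environmental exposures.
`fblmm` turns both kinds of sharing into explicit model components
instead of nuisance correlations to be adjusted out, and combines them
with spike-and-slab selection of individually predictive common variants
and weighted region kernels that let rare variants contribute.

## Model

For a quantitative outcome Y over n individuals,

    Y = X Γ β  +  Σ_m r_m g_m  +  g_f  +  e_f  +  ε

- `X Γ β` — Bernoulli–Gaussian spike-and-slab fixed effects for isolated
  common variants (γ_j ~ Bern(θ₀), β_j ~ N(0, σ_β²));
- `g_m ~ N(0, K_m σ_m²)` — per-region random effects with selection
  indicators r_m ~ Bern(℘) and similarity kernels
  K_m = G_m W_m G_mᵀ / p_m, where the weights W_m (uniform,
  1/√(MAF(1−MAF)) "WSS", or squared beta(1,25) density) up-weight rare
  variants;
- `g_f ~ N(0, K_gf σ_gf²)` — a kinship surrogate for unmeasured genetic
  factors (K_gf = pedigree-expected relationship matrix, MZ twins 1);
- `e_f ~ N(0, K_ef σ_ef²)` — a shared-environment surrogate (K_ef =
  block of ones per family);
- inverse-gamma priors on all variance components.

Inference is coordinate-ascent mean-field variational Bayes with exact
conjugate updates (monotone ELBO), after reparameterising every kernel
through its eigendecomposition Z = QΛ^{1/2}. At prediction time each
component contributes its Gaussian-process conditional mean; subjects
from training families additionally receive the fitted kinship and
family-environment terms, while unrelated subjects get genotype-only
predictions. See `docs/methods.md` for the full treatment.

The package also ships the machinery needed to validate such a model
end to end: a pedigree simulator (founder genotypes over a configurable
MAF spectrum, Mendelian gene dropping, MZ twins), three phenotype
generators (shared-environment-only, genetic-only with an unmeasured
causal gene, and combined), a GLS single-marker pre-screen, a
genotype-only gBLUP baseline, and a replicated benchmark loop.

## Worked example

Simulate a study of 100 nuclear families (400 individuals) in which
shared environment explains 75% of the outcome variance, fit on a random
80% of individuals, and predict the held-out 20%:

```python
import fblmm

study = fblmm.run_scenario(
    "fig2",
    overrides={
        "pedigree_blocks": (("nuclear-2-offspring", 100),),
        "n_variants": 60, "founder_pool": 160,
        "causal_region_sizes": (8, 8, 8), "env_fraction": 0.75,
    },
    seed=42,
)
plan = fblmm.train_test_split(study.genotypes.samples, ped=study.pedigree,
                              fraction=0.2, seed=42)
fit = fblmm.fit_study(study, plan.train_ids, seed=42)
print(f"converged in {fit.n_sweeps} sweeps, ELBO {fit.final_elbo:.1f}")
fracs = fit.variance_fractions()
print(f"shared-environment fraction: "
      f"{fracs['environment'] / (fracs['environment'] + fracs['residual']):.2f}")
preds = fblmm.predict_study(fit, study, plan.test_ids)
y_test = study.phenotypes.table.loc[list(plan.test_ids), "phenotype"].to_numpy()
print(fblmm.pearson_rmse(preds["prediction"].to_numpy(), y_test))
```

Output:

```
converged in 67 sweeps, ELBO -362.0
shared-environment fraction: 0.75
{'pearson_r': 0.7877172885362885, 'rmse': 0.5704783173518085}
```

The model recovers the simulated shared-environment fraction (0.75) and
predicts held-out family members at r ≈ 0.79 — most of it from the
family-design surrogates, since the genotyped variants are non-causal
here. A genotype-only ridge baseline on the same data reaches r ≈ 0.2
(`fblmm.ridge_baseline`).

## Command line

The same pipeline is available as a CLI over plain-text formats
(dosage TSV or PLINK bed/bim/fam, PED pedigrees, region TSV, phenotype
TSV):

```sh
fblmm simulate out/study --preset fig2 --seed 1
fblmm fit out/study.dosage.tsv out/study.ped out/study.regions.tsv \
      out/study.pheno.tsv out/fit.npz --weights wss
fblmm predict out/fit.npz out/study.dosage.tsv out/preds.tsv \
      --pedigree out/study.ped
fblmm benchmark fig2 out/metrics.tsv --replicates 20 --seed 1
```

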