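# contextnets

Sample-specific gene-network inference from per-sample metadata.

Bulk expression cohorts are heterogeneous: every tumor, tissue, or condition
carries its own regulatory wiring, but no single sample contains enough
replicates to fit its own network. `contextnets` resolves this by
*contextualizing* classical Gaussian network estimators: a small neural
encoder `f` maps each sample's context vector `C` (clinical covariates,
mutation calls, immune fractions, ...) to mixing weights
`Z = f(C) ∈ R^K`, and the sample's network parameters are a mixture of `K`
learned archetype matrices,

    θ(C) = Σ_k f(C)_k A_k .

Encoder and archetypes are trained jointly by gradient descent on a
class-specific least-squares loss, so statistical power is shared across
the whole cohort while every sample still receives its own network — and
networks can be emitted zero-shot for contexts never seen in training.

Three network families are supported through one linear parameterization:

- **neighborhood selection** — each gene regressed on all others,
  `ℓ = ‖X − Xθ′‖² + λΣ‖θ′_i‖₁` with a masked diagonal `θ′`;
- **Markov networks** — symmetric regression `θ = γ′ + γ′ᵀ`; under the
  unit-diagonal convention the precision estimate is
  `Ω̂ = −(γ′ + γ′ᵀ)` off the diagonal, and
  `ρ_ij = −ω_ij / √(ω_ii ω_jj)` gives partial correlations;
- **correlation networks** — per-pair univariate regressions whose products
  `θ_ij θ_ji = ρ²_ij` recover squared Pearson correlations.

Around the estimator the package provides the experimental scaffolding a
study of this kind needs: population / cohort / context-clustered baseline
fits under the identical losses, a context-varying Gaussian simulation
benchmark with ground-truth precisions (horizontal vs vertical scaling
grids), expression-MSE evaluation with hold-out-group ("disease-fold")
cross-validation, bootstrap ensembling, and network-based subtype discovery
(Ward clustering of per-sample networks, silhouette model selection,
subtype-vs-rest Welch t-tests, multivariate and pairwise log-rank survival
tests). Synthetic cohort generators make the full pipeline runnable and
testable with no external data.

## Worked example

Recover context-varying precision matrices from single samples. The
generative law is `C ~ Unif[−1, 1]`, `X ~ N(0, [[1, C], [C, 1]])` — 2,000
distinct contexts with **one** observation each, a regime where classical
per-group estimation is hopeless:

```python
import numpy as np
from contextnets import (
    ContextualizedNetworks, FitConfig, GroupingScheme, fit_grouped,
    partial_correlation, reconstruct_precision,
)
from contextnets.simulate import (
    ContextVaryingGaussianSpec, parameter_mse, sample_dataset,
)

spec = ContextVaryingGaussianSpec(n_contexts=2000, samples_per_context=1, seed=7)
contexts, expression, true_precisions = sample_dataset(spec)

cfg = FitConfig(network_class="markov", K=4, hidden_widths=(32,),
                lambda_l1=0.0, seed=3)
model = ContextualizedNetworks(cfg).fit(contexts, expression)

networks = model.predict_networks(np.array([[0.5]]))   # zero-shot context
omega = reconstruct_precision(networks.values)[0]
print(np.round(omega, 3))
print("partial correlation:", np.round(partial_correlation(omega)[0, 1], 3))

prec = reconstruct_precision(model.predict_networks(contexts).values)
print("contextualized parameter MSE:", round(parameter_mse(prec, true_precisions), 5))

pop = fit_grouped(contexts, expression, GroupingScheme("population"), "markov")
prec_pop = reconstruct_precision(pop.predict_networks(contexts).values)
print("population parameter MSE:   ", round(parameter_mse(prec_pop, true_precisions), 5))
```

Output:

```
[[ 1.    -0.503]
 [-0.503  1.   ]]
partial correlation: 0.503
contextualized parameter MSE: 0.00042
population parameter MSE:    0.16289
```

The model was never shown the context value 0.5, yet its precision estimate
matches the ground truth `(1/(1−0.25))·[[1, −0.5], [−0.5, 1]]` after
unit-diagonal rescaling (true partial correlation 0.5). Averaged over all
2,000 samples, the contextualized estimator's unit-diagonal-normalized
parameter MSE is ~0.0004, roughly 400× below the single-network population
fit — the benefit of *horizontal* scaling across contexts when *vertical*
replication within a context is impossible.

## Command line

A thin CLI wraps the library for file-based workflows:

```bash
contextnets simulate --n-contexts 500 --samples-per-context 1 --seed 0 --out sim/
contextnets fit --expression expr.tsv --context ctx.tsv --model markov \
    --archetypes 16 --bootstraps 5 --seed 0 --out model/
contextnets predict --model-dir model/ --context ctx.tsv --out networks.tsv
contextnets evaluate --model-dir model/ --expression expr.tsv --context ctx.tsv --out eval.tsv
contextnets subtype --networks networks.tsv --context ctx.tsv \
    --survival surv.tsv --auto-k --out subtypes/
contextnets benchmark-grid --spec grid.yaml --seed 0 --out grid.tsv
```

All inputs are delimited text (samples × genes expression, samples ×
features context, 3-column survival tables); networks are written in a
long `sample_id, gene_i, gene_j, value, network_class` format.

## Documentation

`docs/methods.md` describes the model, its assumptions, the default
hyperparameters, the synthetic-data generators and what they do and do not
emulate, and the package's numerical conventions and known limitations.
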