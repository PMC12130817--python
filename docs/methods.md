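# Methods

## Model

Each sample carries an expression vector `X ∈ R^p` and a context vector
`C`. We assume `X | C ~ N(0, Σ(C))` and estimate the context-dependence of
the network parameters rather than one network per predefined group. The
estimator has two learned parts:

1. a deterministic context encoder `f` (a multilayer perceptron) mapping
   the encoded context to subtype weights `Z = f(C) ∈ R^K`;
2. a dictionary of `K` archetype matrices `A_k ∈ R^{p×p}`.

The sample-specific parameter matrix is the mixture
`θ(C) = Σ_k f(C)_k A_k`. In the default *linear* mixing mode `Z` is
unconstrained, so emitted networks live in the linear span of the
archetypes; a *simplex* mode (softmax on `Z`) restricts them to the convex
hull instead. Both are exposed because either reading of "mixture" is
defensible; nothing downstream depends on the choice, and all tests run
both where the distinction matters.

### Network classes and losses

All three classes reduce to least-squares objectives in `θ`, which makes
them differentiable, mutually comparable, and proportional to Gaussian
negative log-likelihoods:

| class | predictive form | loss (per sample) |
|---|---|---|
| neighborhood | `x̂ = x θ′`, `θ′ = (1−I)⊙θ` | mean`(x − xθ′)²` + `λ Σ_offdiag |θ′|` |
| markov | `x̂ = x (γ′ + γ′ᵀ)`, zero-diag `γ′` | same residual form, penalty on `γ′` |
| correlation | `x̂_j = x_i θ_ij` for every ordered pair | mean over all `p²` pair residuals |

Diagonal masking is exact (`(1−I)⊙θ`), applied inside the loss and at
prediction, so no model can predict a gene from itself. For the markov
class the stored parameter is `γ′`; the precision estimate is
`Ω̂ = −(γ′+γ′ᵀ)` off the diagonal with ones on it (the unit-diagonal
convention under which the regression coefficients equal negated precision
entries), giving partial correlations `ρ_ij = −ω_ij/√(ω_ii ω_jj)`.
Correlation-class products `θ_ij θ_ji` estimate `ρ²_ij`; they are clipped
to `[0, 1]` only at reconstruction (with a warning), never during
training.

**Reduction convention.** The paper-style objectives are unreduced sums; we
use the *mean* over all residual terms (`n·p`, or `n·p²` for the
correlation class) so losses are comparable across sample and gene counts
and reported MSEs are per-entry. The L1 penalty is `λ ×` the sum of
off-diagonal magnitudes per network, averaged over samples when networks
are sample-specific — for a shared network this is exactly `λ‖θ′‖₁`.
Validation losses and all reported MSEs exclude the penalty.

### Training

Everything is fit end-to-end with hand-written backpropagation in NumPy:
the losses are quadratic in `θ`, `θ` is bilinear in `(Z, A)`, and the MLP
backward pass is standard. The optimizer is Adam.

Defaults (all configurable through `FitConfig`):

| parameter | default | rationale |
|---|---|---|
| `K` (archetypes) | 16 | generous span for real cohorts; experiments here use 4 |
| encoder | 2 hidden layers × 64, ReLU | small MLP; linear encoder available via `hidden_widths=()` |
| `learning_rate` | 1e-2 | the bilinear encoder×archetype objective crawls at smaller rates |
| `max_epochs` / patience | 500 / 25 | early stop on a 20 % validation split, best-val snapshot restored |
| `lambda_l1` | 1e-3 | weak sparsity on the mean-scaled loss |
| `batch_size` | 256 (full batch when n ≤ 1024) | these problem sizes rarely need minibatching |
| standardization | per-gene z-score on the training split | population MSE ≈ 1 then anchors comparisons |

Archetypes initialize near zero (`N(0, 10⁻²)`) and the encoder final layer
starts small, so initial networks are ≈ 0 and early training is stable.
Seed plumbing is explicit: one master seed derives the train/validation
split, weight init, shuffling, and bootstrap resamples through
`SeedSequence([seed, role])`, which is what makes fits bit-reproducible
and model bundles byte-identical across runs.

One consequence of best-validation snapshotting worth knowing: early
stopping acts as shrinkage, so a stopped fit can score *better* than the
exact least-squares solution on held-out rows. Convergence claims (e.g.
the homogeneous-limit equivalence with column-wise OLS) are therefore
checked on fits run to convergence with early stopping disabled; so
configured, the fitted model matches OLS to machine precision.

### Baselines

Population, cohort ("labels"), and context-clustered estimators minimize
the identical class losses on their group's rows. With `λ = 0` the
neighborhood and correlation fits are closed-form least squares, and the
symmetric markov fit is solved exactly from its stationarity conditions
(`offdiag(sym(S − Sθ)) = 0`, `S = XᵀX`, a linear system in the `p(p−1)/2`
free entries) — preferred over a gradient loop so baselines are
oracle-grade. With `λ > 0` a small Adam loop is used. Context clustering
is k-means on the schema-encoded context, with silhouette selection of k
when not specified. Label-based baselines refuse to predict for unseen
groups by raising an explicit error; the hold-out-group harness converts
that into a "not applicable" marker, which is the structurally correct
report (a group-specific model has no model for a group it never saw).

### Bootstrap ensembling

`bootstrap_fit` trains `B` members on with-replacement resamples with
seeds `seed + b`; ensemble networks are entrywise means and the SD across
members provides confidence bands. A `B = 1` ensemble is exactly the
single fit. Note that at the small cohort sizes used in the built-in
experiments, single best-validation fits cluster and generalize slightly
better than bootstrap-averaged ones (resampling perturbs subtype
proportions and each member carries its own overfitting), so the
experiment drivers use single fits and the ensemble is exercised by its
own contracts.

## Evaluation

`expression_mse` scores any per-sample network set against observed
(standardized) expression under the class's own predictive form and equals
the penalty-free training loss on the same rows to 1e-10. The correlation
class averages over all `p²` ordered pairs including the zero-residual
diagonal, so absolute values are comparable only within a class. Relative
MSE divides group means by a named baseline's group means (zero baselines
flagged as undefined, never infinity), and `1 − mean(ratio)` gives the
headline error-reduction number. Hold-out-group cross-validation refits
from scratch with one group excluded and scores only that group's rows.

Parameter-space evaluation compares precision estimates to ground truth
after both sides are rescaled to a unit diagonal (i.e. on the
partial-correlation scale), because the generative truth has diagonal
`1/(1−C²)` while the model's convention fixes the diagonal at 1; the
normalization makes the comparison convention-independent and is
configurable (`normalize=False` compares raw entries).

## Subtyping

Per-sample networks are flattened (all off-diagonal entries for the
asymmetric neighborhood class; upper triangle of the symmetrized matrix
for markov/correlation, to avoid double-weighting), then clustered with
Ward-linkage agglomerative clustering. `k` is matched to a reference
subtyping when one is supplied, otherwise chosen by the best mean
silhouette over `k = 2..10` (ties to the smallest k; identical inputs fall
back to `k = 2` with a warning). Context features are ranked by the
minimum over subtypes of two-sided subtype-vs-rest Welch t-tests —
features that matter equally everywhere therefore do *not* rank, which is
the point. Survival stratification uses the k-group multivariate log-rank
test plus all pairwise tests (minimum pairwise p reported); both are
delegated to lifelines and cross-checked in the test suite against a
brute-force observed-vs-expected enumeration. No multiple-testing
correction is applied to the feature ranking by default (a
Benjamini–Hochberg view is trivial to add downstream); the ranking is
exploratory, not confirmatory.

## Preprocessing

Expression preprocessing follows the standard bulk-TPM recipe:
`log(x + 10⁻³)` (natural log by default; base configurable) and optional
compression to *metagenes* — PCA components fitted on the training split
only and applied frozen to all splits. No batch correction is applied:
network objectives learn to down-weight features that predict nothing
else, so isolated batch components merely inflate all models' errors by a
constant, which cancels in comparisons. Gene filtering is a plain gene-list
file, not a hardcoded panel. All loaders reject duplicate sample ids and
(for expression) missing values outright.

## Synthetic data

Two generators define the package's study conditions.

**Context-varying Gaussian** (`simulate`): `C ~ Unif[−1, 1]` (redrawn
inside `|C| ≤ 0.99` to keep `Σ(C)` well-conditioned),
`X ~ N(0, [[1, C], [C, 1]])`, ground-truth precision
`(1/(1−C²))[[1, −C], [−C, 1]]`. The scaling grid sweeps contexts ×
samples-per-context with 5 replicates per cell and per-cell derived seeds;
grouped baselines get one model per distinct context value. In the deeply
sampled corner (few contexts, ~10³ replicates each) the exact per-group
MLE and the contextualized fit are statistically indistinguishable — both
reach parameter MSE ~10⁻⁴ and their ordering under a single draw is noise;
replicate-averaged means favor the grouped MLE, as they should.

**Planted cohort** (`fixtures`): subtypes sit at centers `c_s` along a
latent axis (default `linspace(−0.8, 0.8)`; configurable, including a
simplex geometry), each subtype's precision is the SPD repair of
`I + c_s·D` where the symmetric direction `D` is rescaled so its largest
off-diagonal entry is a fixed `effect_size` (default 0.8) — normalizing
away what would otherwise be a per-seed lottery in subtype separation.
SPD repair symmetrizes and diagonally loads to condition number ≤ 100.
Context features carry the latent coordinate plus `N(0, 0.05²)` jitter;
an `informativeness` fraction of features is informative, the rest pure
noise. Survival times are exponential with per-subtype hazards (default a
4× ladder) under independent exponential censoring tuned to 20 % censored
in every subtype.

The built-in experiments use: 150 samples/subtype with half-informative
context for subtype discovery; asymmetric centers `(−0.8, 0.4, 0.8)` with
the interior subtype held out for zero-shot generalization (with symmetric
centers the middle subtype's true network *equals* the population average,
leaving nothing to win); 400 samples/subtype for the uninformative-context
negative control, where the contextualized model must not beat the
population fit out of sample and may trail it only by its small
(≤ ~10 %) overfitting cost.

What these generators do **not** emulate: non-Gaussian expression noise,
count-data mean–variance structure, batch effects, missing-not-at-random
metadata, correlated or high-cardinality categorical contexts, and
non-exponential hazards. Passing tests demonstrate the estimator's
mechanics — oracle equivalences, horizontal-scaling recovery, zero-shot
transfer, subtype stratification — not performance on real tumor cohorts.

## Numerical conventions and edge cases

- Masking uses exact multiplication by `(1 − I)`; diagonals are exactly 0.
- `partial_correlation` rejects non-positive diagonals; results are
  invariant to positive rescaling of `Ω`.
- Fits with `n < p` in a group warn (high-variance regime) but proceed via
  pseudoinverse-backed least squares.
- NaN training loss aborts with a diagnostic rather than silently
  continuing; non-finite contexts are rejected at encode time, and a
  feature that was complete at fit time but missing at predict time is an
  error (missingness handling is frozen into the schema at fit).
- Silhouette selection breaks ties toward smaller k; degenerate splits
  (silhouette ≤ 0 or collapsed clusters) warn.
- Zero-variance features on both sides of a subtype split contribute p = 1
  (or p = 0 if the constants differ — perfect separation).
- Model bundles are zip files with fixed timestamps; identical seeds and
  data produce byte-identical bundles.

## Known limitations

- Gradient training provides no exact zeros; reported networks are dense,
  with thresholding left as an explicit post-hoc choice (default: none).
- The correlation-class `ρ̂²` can exceed `[0, 1]` before clipping when the
  two directed coefficients disagree strongly — an indicator of a poor fit
  for that pair rather than a quantity to interpret.
- The encoder's behavior outside the training context hull is an
  extrapolation of an unconstrained MLP; zero-shot claims are strongest
  for contexts inside (or near) the hull, and the hold-out experiments are
  designed accordingly.
- Losses assume zero-mean (standardized) expression; callers bypassing the
  built-in standardization must standardize consistently themselves.
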