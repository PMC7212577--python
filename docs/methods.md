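# Methods

## Model

`mgfa` fits a sparse Bayesian group factor analysis model to data structured
into *M* feature views (data modalities) and *G* sample groups.  For group
*g* and view *m* the observed block is

    Y_gm = Z_g W_m^T + eps_gm,

with factor values `Z_g` of shape (N_g, K), weights `W_m` of shape (D_m, K)
and per-(feature, group) noise.  Gaussian, Bernoulli and Poisson observation
models are supported per view.  Each factor ordinates samples along one
latent axis centered at zero, exactly like a principal component; the
weights say which features move along it and in which direction.

Regularization is symmetric and two-level on both sides of the
factorization:

* **ARD** — a Gamma-precision prior per (factor, view) on weights and per
  (factor, group) on factor values.  It shrinks entire factor columns to
  zero where a factor carries no signal, which is what produces
  *differential* factor activity across views and groups, and it is the
  mechanism by which spare factors are pruned: the user only chooses a
  starting `K`.
* **Spike-and-slab** — elementwise Bernoulli inclusion with a Beta prior on
  the inclusion level, always on for weights and optional for factor values
  (`spike_slab_factors`).  The posterior is parameterized jointly,
  q(s, w) = q(s) q(w | s), which avoids the well-known mean-field pathology
  of factorizing the indicator and the coefficient independently.

With a single group and factor-side regularization disabled
(`ard_factors=False`), the prior structure collapses to the weight-side-only
model: plain N(0, 1) factors with ARD and spike-and-slab on the weights.

## Inference

Mean-field coordinate ascent on the ELBO, sweeping in a fixed canonical
order: local bound parameters (non-gaussian views) → weights per view →
factor values per group → ARD precisions → sparsity levels → noise
precisions.  Every sub-update is the exact conditional optimum, so the ELBO
is non-decreasing up to floating-point round-off; the test suite enforces a
relative tolerance of 1e-8 per sweep.  Missing entries are handled by
restricting every sufficient statistic to observed positions — no
imputation during inference — so arbitrary values placed at masked
positions provably never influence any result.

The spike branch of each spike-and-slab posterior is the expected prior
N(0, 1/E[alpha]) with the variance frozen at the time of the coefficient
update (`var0`); both the ELBO and the ARD update use this stored value,
which keeps every step an exact coordinate-ascent move.

**Initialization** is deterministic: factor means are the first K principal
component scores of the group-stacked, view-concatenated data matrix
(missing entries zero-filled for the decomposition only, columns centered),
standardized to unit variance per factor.  Weights start at zero with unit
slab variance and inclusion probability 1/2; Gamma/Beta posteriors start at
their priors.  Random restarts with ELBO-based model selection are possible
in principle, but the deterministic path removes the random component and
is the default — identical options always give identical fits.  A wrapper
for seed-randomized restarts was judged unnecessary given the deterministic
default and is not provided.

**Non-Gaussian views.**  Bernoulli data use the Jaakkola–Jordan logistic
bound; Poisson data use a uniform-curvature quadratic bound around an
expansion point ζ for the log-likelihood under a softplus rate,
kappa(y) = 1/4 + 0.17·y (1/4 bounds softplus'' and 0.167 < 0.17 bounds the
curvature of −log softplus, verified numerically).  Both bounds are exact
at their tightness point and are re-expressed as Gaussian
pseudo-observations (pseudo-data, pseudo-precision) so the Gaussian update
machinery is reused unchanged.  ζ* = sqrt(E[x²]) (Bernoulli) and
ζ* = E[x] (Poisson) maximize the respective bounds.  Non-Gaussian views add
one local parameter per observed entry and slow training; transforming to
approximately Gaussian values (e.g. M-values for methylation rates) is
preferred whenever defensible.

**Stochastic inference** (`mode='svi'`) partitions each group's samples
into ceil(1/fraction) stratified batches per epoch (so small groups are
never starved), updates local variables exactly on the batch, and moves
every global posterior by interpolating natural parameters between the
current value and the full-data optimum estimated from batch statistics
scaled by N_g/|batch_g|:

    eta_new = (1 − rho_t) eta_old + rho_t eta_hat,
    rho_t   = lr · (1 + kappa·t)^(−3/4),

with t counted per update step (per batch, not per epoch).  Defaults:
batch fraction 0.5, starting learning rate 1.0, forgetting rate 0.25.  With
kappa > 0 the schedule satisfies the Robbins–Monro conditions; with a full
batch and rho = 1 each update is bit-identical to the coordinate-ascent
sweep (tested).  SVI pays off when samples greatly outnumber features;
otherwise full-batch VI is preferable.

**Convergence** is declared when the full-data ELBO changes by less than
`convergence_tol` between iterations (epochs in SVI mode — the ELBO is
always evaluated on the full data so the rule is comparable between modes).
The default rule is the absolute difference with tol 1e-4; because that
rule is scale-dependent, `tol_scale='relative'` divides by |ELBO|, and the
test and validation scripts use the relative form.

**Factor pruning.**  During training a factor is dropped only when it has
collapsed to an effective zero (largest |E[z]| and variance-explained proxy
both below 1e-10).  User-facing pruning is explicit: `prune_factors`
removes factors whose R² is below a threshold (1% by default in the CLI) in
every (group, view) block and renumbers the rest by total variance
explained.

## Priors and defaults

| parameter | default | meaning |
|---|---|---|
| ARD Gamma (a, b) | (1e-5, 1e-5) | broad, E[alpha] = 1 |
| noise Gamma (a, b) | (1e-5, 1e-5) | broad, E[tau] = 1 |
| sparsity Beta (a, b) | (1, 1) | uniform inclusion level |
| `n_factors` | 10 | starting K; ARD shrinks the excess |
| `convergence_tol` | 1e-4 (absolute) | ELBO difference rule |
| `batch_fraction`, `learning_rate`, `forgetting_rate` | 0.5, 1.0, 0.25 | SVI schedule |

All hyperparameters are exposed in `PriorHyperparameters` /
`TrainingOptions`.  Spike-and-slab on factor values defaults to off (ARD on
factors remains on), which keeps the factor posterior dense and
interpretable while still allowing per-group shrinkage.

## Preprocessing

Gaussian views are centered per feature within each group, over observed
entries only, before fitting: intercept (group-offset) effects are removed
so factors capture shared axes of variation rather than mean differences
between groups.  Bernoulli/Poisson views are never centered (it would break
their support).  Highly-variable-feature selection ranks features by
variance pooled across groups after per-group mean removal — group offsets
therefore do not dominate the ranking — with ties keeping the earlier
feature.  Count assays should arrive size-factor normalized and
variance-stabilized; coverage-based assays (methylation, accessibility) are
supported through the binomial-rate M-value transform
M = log2(rate/(1−rate)), with the rate clamped to [0.001, 0.999] to keep
fully (un)methylated features finite — the clamp constant is our choice —
and entries under a minimum read count returned as missing.

## Variance decomposition

R² of factor k in block (g, m) is the conventional coefficient of
determination of the factor's rank-1 reconstruction against the centered
observations over observed positions:

    R²_gmk = 1 − Σ (Y − E[z_k] E[w_k]^T)² / Σ Y²,

and the per-block total uses all K factors jointly.  This is the only
reading under which a perfect fit gives R² = 1.  Per-factor values are not
additive across factors (factors need not be orthogonal); negative raw
values — a factor whose rank-1 term adds more variance than it removes —
are clipped to zero for reporting, with the raw value retained.  For
non-Gaussian views R² is computed on the pseudo-data scale implied by the
local bounds, where the factorization itself lives.

## Enrichment

Per factor and view, each gene set is tested by a Welch (unequal-variance)
two-sample t-test of the foreground features' weights against all remaining
features' weights — absolute weights by default, signed optionally —
followed by Benjamini–Hochberg adjustment across the sets of that factor
and a significance flag at FDR 1%.  Welch rather than pooled-variance is a
deliberate choice: foreground sets are small and their weight variance
differs from the background's.  Under exchangeable weights the flag rate
stays below the nominal level (calibration test).

## What the simulator does and does not emulate

The simulator draws exactly from the generative model: designed per-group
and per-view activity scales, spike-and-slab weights, Gaussian noise or
logistic/softplus links, and missing-completely-at-random masks, with
per-group/per-view random streams derived from one root seed.  It does
**not** emulate count overdispersion, batch effects within groups, doublets,
or informative missingness.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data violations of them.

Validation study sizes were chosen to keep the full suite fast on a single
CPU: activity-pattern recovery uses K=5 factors with a designed on/off
pattern across G=3 groups and M=2 views at noise variance 4 — a weak-signal
regime (each factor explains a few percent of variance) where factor-side
shrinkage is actually load-bearing; with strong signal the weight-only
ablation recovers the same pattern and the comparison is uninformative.
Stochastic/full-batch consistency uses N=2000 samples and D=500 features,
where a VI iteration is still cheap but batching is meaningful.

## Numerical choices

* Inclusion probabilities are clipped to [1e-12, 1−1e-12] before logit
  interpolation; entropies use `xlogy`, so exact 0/1 probabilities are safe.
* Poisson rates are floored at 1e-300 before taking logs.
* The degenerate all-zero data matrix initializes all factor scores to zero
  rather than failing the SVD path.
* A requested `n_factors` above the feasible rank of the concatenated data
  is reduced with a warning.
* Ties in feature variance (selection) and weight magnitude (ranking) keep
  the original feature order via stable sorts.
* Non-finite intermediates abort with a diagnostic naming the offending
  update.

## Known limitations

* Factors capture linear structure only; strongly non-linear manifolds are
  better served by passing the exported factor table to a non-linear
  embedding downstream.
* Features are treated as independent in the priors; no structure between
  features (pathways, genomic proximity) is modeled.
* All views must be measured on the same samples; there is no anchoring of
  disjoint sample sets.
* Missingness is assumed uninformative.
* The HDF5 container layout is self-describing and versioned but is not
  byte-compatible with other factor-model toolkits.
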