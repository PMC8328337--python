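# Methods

## Model

`phlsm` fits a logistic latent-distance model for a directed binary network
Y on n nodes.  The log-odds that node i follows node j is

    eta_ij = beta0 + beta' x_ij - ||z_i - z_j|| / gamma_j,

with

- z_i in R^d (default d = 2) latent positions, z_i ~ N_d(0, sigma2 I)
  a priori, sigma2 ~ InverseGamma(nu, phi);
- gamma = (gamma_1, ..., gamma_n) a *popularity* vector on the open simplex
  (sum_j gamma_j = 1, gamma_j in (0,1)).  gamma_j divides the latent
  distance in every edge pointing *into* j, so a large gamma_j makes node j
  easy to follow regardless of who is looking: this carries the in-degree
  heterogeneity of scale-free "follower" networks.  As gamma_j -> 0 the
  probability of being followed vanishes; at gamma_j = 1 the term reduces
  to the classical latent space model.  Out-degree heterogeneity is
  deliberately not modeled (real platforms cap how many accounts one can
  follow, so out-degrees are comparatively homogeneous);
- x_ij >= 0 symmetric pairwise dissimilarities built from node attributes:
  |log a_i - log a_j| for continuous attributes (after columnwise min-max
  normalisation into [epsilon, 1], epsilon = 1e-3, so the log is finite)
  and the indicator 1{label_i != label_j} for categorical ones.  A negative
  beta_k therefore means homophily on attribute k;
- beta0 is fixed at 1 and sum_j gamma_j = 1; both are identification
  constraints, not free parameters;
- edges are conditionally independent Bernoulli(logistic(eta_ij)) given
  all parameters, and y_ii = 0.

Two penalties on beta are available: a Normal prior beta_k ~ N(0, 1/tau_k^2)
with tau_k^2 ~ Gamma(xi_tau, delta_tau) (Bayesian ridge, the default for
p << n) and a Laplace prior beta_k ~ Lap(0, 1/lambda_k) with
lambda_k ~ Gamma(xi_lam, delta_lam) (Bayesian adaptive LASSO for large p;
the per-coefficient Gamma hyperprior plays the role of the adaptive
weights, so no pilot estimate is needed).  Because the Laplace/Gamma pair
is conjugate, lambda_k has the exact Gamma(xi_lam + 1, delta_lam + |beta_k|)
full conditional; the ridge precision has the exact
Gamma(xi_tau + 1/2, delta_tau + beta_k^2/2) full conditional.

For networks with community structure the latent prior can be switched to
a G-component Gaussian mixture (weights on the simplex, conjugate
Dirichlet/Normal/Inverse-Gamma hyperpriors); label switching in the stored
draws is resolved afterwards by the exhaustive KL-minimizing relabeling in
`relabel_clusters` (G <= 8).

## Posterior computation

Inference is MH-within-Gibbs (`run_sampler`).  Per iteration:

1. each z_i: Gaussian random-walk MH against the full conditional
   (2(n-1) Bernoulli terms + latent prior);
2. sigma2: exact InverseGamma(nu + n, phi + 1/2 sum ||z_i||^2) draw
   (for d = 2; in mixture mode per-component variances are drawn instead);
3. each beta_k: random-walk MH (Normal walk under ridge, Laplace walk under
   lasso; both symmetric proposals);
4. tau_k^2 or lambda_k: exact Gamma draws;
5. gamma: one joint Dirichlet(M gamma) proposal accepted or rejected as a
   whole, with the asymmetric-proposal Hastings correction.  The default
   concentration M = 5e6 matches the n = 500 study design; for much
   smaller networks M should be scaled down (the toy-model validation
   below uses M = 500) or the move barely leaves its starting point.

Numerical choices:

- All kernels work in log space; Bernoulli terms use the log1p-exp
  softplus form and saturate analytically beyond |eta| > 37, so no edge
  probability is ever materialised.
- The hot loops (z sweep, beta sweep, gamma move) are numba-compiled and
  maintain three caches: the distance matrix D, the covariate part of the
  predictor C = beta0 + X beta, and the per-pair log-likelihood matrix L.
  A proposal then costs one fresh Bernoulli term per affected pair.  The
  per-iteration log-likelihood trace accumulates accepted deltas and is
  recomputed from scratch every 1000 iterations to cancel floating-point
  drift.
- Random-walk step sizes (z step default 0.05*sqrt(sigma2_init), beta step
  0.1) are Robbins-Monro adapted during burn-in only, targeting ~30%
  acceptance per block (per coefficient for beta), then frozen, so the
  monitored chain is exact MH.
- Identifiability of Z: latent positions enter only through distances, so
  the posterior is invariant under rigid motions.  Stored draws are
  aligned to the initial MDS configuration by orthogonal Procrustes
  (translation + rotation/reflection, no scaling).  The alignment is
  applied to the *stored snapshot only*, never to the evolving chain
  state: the likelihood is translation-invariant but the N(0, sigma2 I)
  prior is not, and re-centering the state each iteration measurably
  biases sigma2 (and hence every posterior distance) downward.  With
  storage-only alignment all posterior means on a 4-node toy agree with an
  importance-sampling oracle within Monte-Carlo error.
- Initial values: classical MDS on min-symmetrized geodesic distances
  (unreachable-in-both-directions pairs capped at the largest finite
  distance + 1, everything rescaled by 1/n); gamma_j^0 =
  (1 + d_j^in)/(n + sum_h d_h^in); sigma2^0 = (1/2n) sum ||z_i^0||^2, which
  also sets phi (so E sigma2 = phi at nu = 2); beta^0 from a fixed-intercept
  logistic regression (offset 1, latent terms omitted), falling back to 0
  under separation.  The MDS symmetrization d(i,j) <- min(d(i,j), d(j,i))
  is bounded and rank-preserving on disconnected samples.
- Default hyperparameters: nu = 2; delta_tau = 0.05, delta_lam = 0.1;
  xi_tau = 4 / xi_lam = 8 for categorical covariates and 2 / 4 for
  continuous ones; flat Dirichlet(1, ..., 1) on gamma.

## Synthetic data

`simulate_network` draws from the model itself: alpha_i i.i.d. from the
truncated discrete power law P(l) ∝ l^-theta on {1..l_max} (l_max = n by
default; the truncated zeta sum is the only normalisation that yields a
probability distribution), gamma ~ Dirichlet(alpha), z_i ~ N_2(0, sigma2 I)
with sigma2 = 3e-4, attributes N(0,1) or Bernoulli(0.5), independent
Bernoulli edges.  Small theta gives heavy-tailed alpha, hence dominant
hubs; the in-degree CCDF is close to linear on log-log axes.  The three
benchmark designs are exposed as presets: `table1` (n = 500, no
covariates, theta in {1.7, 2.0, 2.3}), `example2` (n = 500, theta = 2,
beta = (0.5, -1) on one continuous and one binary attribute), and the
sparse designs `lasso40` / `lasso150` (n = 50, theta = 2; 4 of 40 and 14
of 150 coefficients active, actives alternating +-1, binary attributes in
the first half and continuous in the second).

What the generator does *not* emulate: transitive closure beyond what
symmetric latent distances induce, degree assortativity, attribute
distributions with outliers or missingness, and any dependence between
attributes and latent positions.  Passing recovery tests on these
simulations therefore demonstrates internal consistency of model +
sampler, not robustness on real social networks.

A caveat found while validating the simulator: under this generative
process (2-D latent Gaussians at sigma2 = 3e-4, beta0 = 1), the
conditional reciprocity P(y_ji = 1 | y_ij = 1) of a sparse network is
bounded near 0.28 even in the most favourable (constant-gamma) case —
numerical integration of E[p^2]/E[p] over the Rayleigh distance density
shows the bound, and heterogeneous gamma only lowers it.  Empirical
reciprocities cited for this design that exceed the bound (at theta = 2.3)
cannot be reproduced by any parameterisation of the printed model; a 1-D
latent geometry, whose distance density does not vanish at zero, matches
them closely.  The package implements the model as specified (d = 2) and
reports what it actually produces.

## Evaluation

- Link prediction is in-sample: P-hat is the Monte-Carlo mean of
  logistic(eta_ij) across stored draws (a posterior-predictive average,
  not the probability at posterior-mean parameters), compared against the
  training adjacency.  TCR/TPR/FPR use a 0.5 threshold by default (the
  threshold is exposed); AUC is the rank-based Mann-Whitney statistic with
  midrank ties.
- Variable selection: a coefficient is "kept" when its 95% equal-tailed
  credible interval excludes 0.  A shrinkage posterior never produces
  exact zeros, and the interval rule is the standard surrogate; C / IC /
  Under- / Over- / Correct-fit aggregate keeps over replicates.
- Recovery diagnostics: MSE of posterior-mean pairwise distances and of
  gamma, per-edge estimated/true ratio samples, and the Spearman
  correlation between posterior-mean gamma and observed in-degrees.

## Validation scales and observed behaviour

The test suite runs the expensive checks at reduced scale so the whole
suite stays within a desk-scale budget: sampler correctness on a 4-node
model (2e5 iterations against a 2e6-draw importance-sampling oracle, plus
likelihood-off prior recovery); parameter recovery on 5 replicates of the
two-covariate design at n = 150 with 20 000 iterations (10 000 burn-in);
variable selection on 5 replicates of the n = 50, p = 40 sparse design
with 20 000 iterations under both penalties.  At n = 150 the in-sample AUC
is ~0.96 and the gamma/in-degree rank correlation ~0.93; coefficient
estimates show a mild attenuation toward zero (mean bias up to ~0.1 on a
coefficient of magnitude 1).  The attenuation shrinks with network size —
with many more informative pairs the latent field is pinned down and can
no longer absorb covariate signal — and is a finite-sample property of
the model, not a sampler artefact (truth-initialised chains land in the
same place, and the toy-scale oracle comparison is exact).

## Known limitations

- Only the Euclidean distance is implemented (the interface would admit
  others).
- SCAD/MCP penalties, weighted or dynamic networks, and held-out edge
  splits are out of scope.
- The exhaustive relabeling is factorial in G and refuses G > 8.
- The Dirichlet popularity move updates all n components jointly; for
  very large n its acceptance decays and M must be tuned accordingly.
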