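# phlsm — penalized homophily latent space models for directed networks

`phlsm` fits Bayesian latent-distance models to directed binary networks
whose in-degrees are heavy-tailed — follower graphs, citation networks,
directed interaction networks in systems biology.  It is aimed at
practitioners who want interpretable node embeddings, link prediction and
attribute-effect estimates from a single generative model, together with a
simulator for benchmarking.

## Model

The probability that node *i* follows node *j* is logistic in

    eta_ij = beta0 + beta' x_ij − ||z_i − z_j|| / gamma_j,

where `z_i ∈ R^2` are latent positions with prior `N(0, sigma² I)`,
`gamma` is a popularity vector on the simplex (`sum_j gamma_j = 1`;
dividing the distance by `gamma_j` makes popular nodes easy to follow and
carries the power-law in-degree heterogeneity), and `x_ij ≥ 0` are
symmetric pairwise dissimilarities built from node attributes
(`|log a_i − log a_j|` for continuous, `1{label_i ≠ label_j}` for
categorical) so that a *negative* coefficient means homophily.  `beta0` is
fixed at 1 for identification.  Coefficients carry either a Normal prior
with Gamma precisions (Bayesian ridge) or a Laplace prior with
per-coefficient Gamma rates (Bayesian adaptive LASSO, for
high-dimensional attributes).  Inference is Metropolis–Hastings within
Gibbs with a joint Dirichlet proposal for `gamma`; latent draws are
Procrustes-aligned to a classical-MDS initialization.  See
`docs/methods.md` for the full specification, priors, initialization and
numerical choices.

## Worked example

Simulate a 150-node network from the model (power-law popularity,
`theta = 2`, one continuous and one binary attribute with true
`beta = (0.5, −1)`), fit it, and evaluate:

```python
import phlsm

sim = phlsm.simulate_network(phlsm.SimulationSpec(
    n=150, theta=2.0, sigma2=3e-4, beta=(0.5, -1.0),
    attr_types=("continuous", "binary"), seed=42))

cfg = phlsm.MCMCConfig(burn_in=8000, monitor=12000, thin=10, seed=7)
samples = phlsm.run_sampler(sim.net, sim.X, cfg)
print(samples.summary().head(3).to_string(index=False))

P = phlsm.posterior_mean_probs(samples, sim.X)
auc, _ = phlsm.roc_auc(phlsm.PredictionResult(P, sim.net.adjacency))
rec = phlsm.recovery_metrics(samples, sim.truth, sim.net)
```

Output (about a minute on one core):

```
  param      mean       sd      q2.5       q50     q97.5
beta[1]  0.542327 0.040819  0.464539  0.540252  0.624877
beta[2] -0.978447 0.062114 -1.096179 -0.979063 -0.857078
 sigma2  0.000343 0.000032  0.000286  0.000340  0.000413
in-sample AUC = 0.957, Spearman(gamma-hat, in-degree) = 0.941
```

Both coefficients are recovered (the binary attribute is correctly read
as homophilous, `beta_2 < 0`), the latent-variance estimate brackets the
generating value `3e-4`, fitted probabilities separate edges from
non-edges (AUC 0.96), and the posterior-mean popularity ranks nodes
almost exactly as their observed in-degrees do.

The same pipeline is scriptable from the shell:

```sh
phlsm simulate --preset example2 --reps 1 --seed 1 --out sim/
phlsm fit --network sim/rep001_edges.tsv --attrs sim/rep001_attrs.csv \
          --profile quick --seed 1 --out run/
phlsm evaluate --run run/ --network sim/rep001_edges.tsv \
               --attrs sim/rep001_attrs.csv --truth sim/rep001_truth.json \
               --out metrics.json
phlsm predict --run run/ --network sim/rep001_edges.tsv \
              --attrs sim/rep001_attrs.csv --out pred/
```

`fit` writes compressed posterior samples, a summary CSV and a JSON run
manifest (seed, config hash, input digests, acceptance rates) sufficient
to reproduce the run bit-for-bit.

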