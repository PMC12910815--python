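# pairednb

Joint negative binomial latent factor models for paired two-site
microbiome count data.

## The problem

Microbiome studies often sequence the same subjects at two body sites
(e.g. vaginal swab and catheterized urine).  The two count tables are not
independent: unobserved subject-level effects push a taxon's abundance up
or down at both sites at once.  Fitting each site separately wastes that
shared signal and loses efficiency exactly when the cross-site association
is strong; transforming counts for a Gaussian mixed model forces a
pseudocount choice that the estimates turn out to be very sensitive to.

`pairednb` models the counts directly.  For one taxon with count
`y[s,i]` in sample `i` at site `s ∈ {1,2}` and sequencing depth `N[s,i]`:

    y[s,i] ~ NB(mu[s,i], alpha_s),      Var = (1 + mu alpha) mu,
    mu[s,i] = exp(gamma_i + log N[s,i] + x_i' beta_s),
    gamma_i ~ N(-phi^2/2, phi^2).

The shared latent factor `gamma_i` is the sole source of cross-site
correlation; its centering makes `E exp(gamma) = 1`, so `phi^2` is a pure
association strength: `phi^2 = 0` reduces the joint model (JNBM) to two
independent NB regressions (SNBM).  Two extensions let association vary
across samples: JNBM_SG indexes `phi^2` by an observed group, and
JNBM_Mix infers groups through a finite normal mixture with ordered
variances `phi^2_1 < … < phi^2_L`.  Inference is fully Bayesian via a
Pólya-Gamma-augmented Gibbs sampler (the augmentation makes the
regression coefficients and latent factors conditionally Gaussian);
posterior predictive draws support cross-site imputation — predicting a
sample's counts at one site from its counts at the other — evaluated by
an imposed-zero 10-fold cross-validation harness with DAR and
Kullback-Leibler composition residuals.

See `docs/methods.md` for the sampler details and design choices.

## Worked example

`examples/01_fit_joint_model.py` simulates strongly associated pairs
(`phi^2 = 5`, n = 300) and fits the joint and separate models:

```
n = 300 pairs per replicate, 3 replicates
posterior mean phi^2 per replicate: [5.49 4.6  4.9 ] (truth 5)

site              1                   2
covariate         2         3         2         3
model
JNBM       0.000314  0.054124  0.000074  0.098565
SNBM       0.000577  0.510926  0.000338  0.456669

Cells are MSEs of the covariate coefficients (sites 1-2, covariates 2-3).
The joint model's smaller errors are the efficiency gained by modeling
the shared latent factor.
```

The posterior mean of `phi^2` recovers the generating association
strength, and the joint model's coefficient MSEs are 2-5 times smaller
than the separate model's — the efficiency that is lost when a real
cross-site dependence is ignored.

The other example scripts demonstrate cross-site prediction
(`02_cross_site_prediction.py`), the pseudocount-sensitivity benchmark
against the Gaussian mixed baseline
(`03_benchmark_vs_gaussian_baseline.py`), and the mixture model's
recovery of heterogeneous association levels with the L-sensitivity scan
(`04_mixture_association_levels.py`).

## Command line

A thin CLI wraps the library:

```sh
pairednb simulate --scenario table2_lomax --reps 1 --seed 7 --out sim/
pairednb fit --site1 sim/rep000_site1_counts.tsv \
             --site2 sim/rep000_site2_counts.tsv \
             --metadata sim/rep000_metadata.tsv \
             --taxon table2_lomax --model JNBM --out summary.tsv
pairednb predict ... ; pairednb evaluate ... ; pairednb benchmark ...
```

Count tables are tab-separated, taxa in rows, samples in columns; depths
are recomputed as per-sample column sums at load time.  `--paper-scale`
switches the benchmark/fit commands to production-length chains
(1,000,000 iterations, 500,000 burn-in).

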