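# Methods

## Model

`epibayes` fits the linear model

```
y = mu + Z theta + eps,        eps ~ N(0, sigma_eps^2 I_N)
```

where the columns of `Z` are partitioned into named covariate *groups* —
typically SNP dosages, methylation probes, and fixed covariates such as age
and sex — and every column (and the phenotype) is centred and scaled to unit
sample variance.  Each effect carries a grouped spike-and-slab Gaussian
mixture prior:

```
theta_j | group g  ~  pi_g0 * delta_0 + sum_l pi_gl * N(0, sigma_g^2 * C_gl)
```

The slab variances are a common per-group scale `sigma_g^2` times a strictly
increasing set of dimensionless constants `C_g` (e.g. `{0.0001, 0.001, 0.01}`
for SNPs and `{0.01, 0.1, 1}` for probes on cohort data: methylation effects
on standardized traits are typically an order of magnitude larger than
individual SNP effects, and the separate group scale and proportions let the
model resolve both without one swamping the other).  The mixture proportions
`pi_g` (spike included) have a Dirichlet prior, all-ones by default, and the
variance components have weakly informative scaled inverse-chi-square priors
with `v0 = s0sq = 0.001`.

## Inference

Posterior sampling is single-site Gibbs with residual updating.  With the
residual vector `eps = y - mu - Z theta` held in memory, updating one effect
means forming the partial residual `ytilde = eps + Z_j theta_j` implicitly,
computing the scalar `Z_j' ytilde`, scoring the spike and every slab by its
log marginal likelihood,

```
score_0 = log pi_g0
score_l = log pi_gl - log(1 + s_l Z_j'Z_j / s_e)/2
          + (Z_j'ytilde)^2 s_l / (2 s_e (s_e + s_l Z_j'Z_j)),
          s_l = sigma_g^2 C_gl,  s_e = sigma_eps^2,
```

sampling a component from the normalized scores (computed through
differences to the best score, so no overflow is possible), and — when a
slab wins — drawing the effect from its conjugate normal conditional
`N(Z_j'ytilde / d, s_e / d)` with `d = Z_j'Z_j + s_e/s_l`.  Each update is
O(N) and a full sweep O(N·M).  The effect-update order is reshuffled every
iteration, which in this scheme is what keeps the chain mixing acceptably
for correlated columns.  The intercept, the residual variance
(`Inv-ScaledChi2(v0+N, (eps'eps + v0 s0sq)/(v0+N))`), each group scale
(`Inv-ScaledChi2(v0+m_g, (S_g + v0 s0sq)/(v0+m_g))` with
`S_g = sum theta_j^2 / C_mix(j)` over the group's in-model effects — the
division by the mixture constant identifies `sigma_g^2` as the common
scale), and each `pi_g` (`Dirichlet(prior + occupancy counts)`, spike count
included) complete one iteration.

Numerical choices: variances are floored at 1e-12; chi-square draws at
near-zero degrees of freedom are clipped at 1e-100 so the vague prior's
heavy tail stays finite; the residual vector is recomputed in full every 100
iterations, and the maximum deviation between the maintained and recomputed
residual is tracked every iteration and stored in the chain metadata (the
test suite requires it below 1e-8).  Chains are initialized with all effects
in the spike, `mu = 0`, half the phenotypic variance in the residual and
half split evenly across group scales, and `pi` at the mean of its full
conditional given the all-spike assignment
(`Dirichlet(prior + (M_g, 0, ..., 0))`, spike mass ~ `M_g/(M_g+L+1)`).  The
last point matters: starting `pi` at its *prior* mean (spike mass
`1/(L+1)`) would contradict the all-spike effect state — with the weak
slabs nearly likelihood-indifferent for null columns, most of the design
then enters the model in the first sweep and the chain begins inside a
degenerate massively-polygenic mode that inflates the captured variance
and can ratchet into full residual-variance collapse.  The consistent
sparse start keeps model entry governed by evidence from the first
iteration.  Parallel
chains multiply the initial variances by {0.5, 1, 2, 4} to give
overdispersed starts, and each chain's RNG stream derives from
(seed, chain_id), making every run bit-reproducible.

The whole chain runs inside a single numba-compiled kernel; the same
conditional draws also exist as plain-numpy functions, which the test suite
checks against closed forms, numerical quadrature of the marginal
likelihood, and the exact joint multivariate-normal conditional, and the
kernel is in turn checked against those reference updates on a small design.

## Variance partitioning

Per saved sample the phenotypic variance is partitioned into the *realized*
variance captured by each group's predictor, `Var(Z_g theta_g)`, plus the
residual variance, all normalized by their sum; summaries are posterior
means with equal-tailed 95% credible intervals.  We deliberately report the
realized quantity rather than the prior-scale hyperparameter `sigma_g^2`:
with a mixture grid whose weakest slab is nearly likelihood-indifferent for
null columns (e.g. `C = 1e-4` at N=1000), slab occupancy and `pi` perform a
slow random walk and the hyperparameter decouples from the variance the
group actually captures, whereas `Var(Z_g theta_g)` is what "variance
attributable to the probes" means and is the quantity the benchmark
scenarios recover.  A per-(group, mixture) decomposition (sum of squared
in-model effects per slab, with occupancy counts) is also provided.

## Synthetic data

The generator emulates a whole-blood methylation array measured on a
K-cell-type mixture (default K=5):

* Cell proportions: each individual's row of `R` is
  `Dirichlet(sp * base_proportions)` (uniform base by default).  Larger
  `sp` means *less* cell-composition variability; the benchmark default
  `sp = 1000` gives per-cell-type proportion SDs of ~0.013, so phenotype /
  cell-proportion confounding is mild — the correlation-norm regime the
  headline scenarios probe.  Dirichlet rows that underflow at tiny
  concentrations are redrawn.
* Probe levels: a fraction `p` of probes are differentially methylated
  (DMPs).  A DMP's cell-type mean levels are truncated-normal draws (support
  [0, 1]) around the array base level (0.5) with spread `tau`; every
  individual's cell-specific level is a further truncated-normal draw around
  that mean with spread `indiv_sd` (default `tau`), and the noiseless matrix
  is `M_ij = sum_k R_ik s^(i)_kj`.  Non-DMPs sit exactly at the base level
  in every cell type.  Setting `indiv_sd = 0` recovers the pure mixture
  `M = R S`, in which the noiseless matrix has rank K: every phenotype built
  from it is then a function of cell composition alone and causal probes are
  unidentifiable in principle.  The individual-level variation is what makes
  probe-specific signal (and hence causal-probe recovery) possible at all,
  and is the behaviour of the reference-based simulators this generator
  emulates; it is also what couples genotypes to *individual* methylation
  below.  What passing tests on these data do **not** show: robustness to
  array normalization artefacts, batch effects, probe-specific measurement
  error distributions, or realistic LD among SNPs — none of which are
  generated.
* Observation noise: i.i.d. `N(0, vartheta^2)` on every entry.
* Sparse phenotype: `n_causal` probes drawn from the DMPs (uniformly, or
  ranked by correlation with cell proportions to induce stronger
  confounding) receive `N(0, 0.5/100)` effects; the realized genetic-value
  vector is rescaled so its sample variance is exactly the design fraction
  `ve`, and the residual is orthogonalized to it — the stated variance
  explained (default 60%) is thereby the exact generative truth rather than
  an expectation.  The drawn effect variance and the design `ve` are not
  mutually consistent in general; rescaling the realized vector is the
  reconciliation this package adopts, and the applied scale factor is
  recorded in the dataset metadata.
* Genotypes: for each causal probe, a SNP column is drawn
  `Binomial(2, logistic(c * M_ij - 10))` with `c ~ Uniform(20, 25)` per
  column, tying allele counts to that probe's methylation level; realized
  genotype–methylation correlations span roughly 0 to 0.6 depending on
  where the probe's level places the logistic operating point.  Remaining
  SNPs use independent base-level draws (same allele-frequency spectrum, no
  coupling).  Centring the DMP level distribution at the base level is what
  makes this coupling live: with levels near zero the logistic success
  probability is ~1e-4 and every genotype column would be monomorphic.
  Monomorphic columns (possible at small N) are redrawn by default.
* Joint phenotype: `y = O b_cpg + X b_g + eps` on the standardized observed
  matrices, with 100 probe effects `N(0, 0.5/100)`, 100 large SNP effects
  `N(0, 0.2/100)` on the coupled columns, 900 small SNP effects
  `N(0, 0.1/900)`, and residual variance 0.2 — expected shares
  (0.5, 0.3, 0.2).  Realized shares are recorded in the metadata.
* The full factorial scenario grid (one axis varied at a time around
  p=0.15, tau=0.07, sp=1000, vartheta=0.01; the noise axis builds the
  phenotype on the noisy matrix) enumerates 17 settings x 15 replicates =
  255 datasets and is runnable at any reduced N, M.

## Posterior summaries, enrichment, prediction

Inclusion probability (PIP) is the fraction of saved samples with the
effect in any slab.  Convergence is monitored by the Geweke z score (first
10% vs last 50% of a chain, spectral-density standard errors via a
Bartlett-window estimate at frequency zero with lag cutoff ~2 n^(1/3)) and,
across chains, rank-normalized split R-hat (arviz); diagnostics undefined
on constant chains are reported as NaN rather than raised.

Term enrichment is computed per saved sample as `p.PVE / p.Term`: the
term's share of total in-model squared effects over its share of in-model
probes mapped to any term.  Samples where no in-model probe maps to the
term are excluded from that term's enrichment distribution (the ratio is
undefined) but still count toward its inclusion probability.  A term is
called enriched only when its IP exceeds 0.95 **and** at least 95% of its
enrichment posterior lies outside the region of practical equivalence
(0.5, 1.5) on a single side; split mass is not significant, and fewer than
20 defined samples yields an "insufficient" verdict rather than a guess.
Credible intervals are equal-tailed 95% throughout.

Prediction multiplies posterior-mean effects (spike samples averaged as
zero) into the target cohort's internally standardized marker readings;
accuracy is the squared correlation with the standardized target phenotype
(an adjusted variant is available) plus the slope and SE of regressing the
phenotype on the predictor.  Training columns absent from the target are
dropped and the lost absolute effect mass logged.

## Benchmark protocol sizes

The packaged protocols run a desk-scale version of the simulation study:
N=1000 individuals, M=10,000 probes, 100 causal probes at `ve = 0.6`, and
5000-iteration chains (2500 burn-in, thinning 5) with probe mixture
constants (0.0001, 0.001, 0.01, 0.1); the joint scenario uses 5000 probes +
5000 SNPs with SNP mixtures (0.00001, 0.0001, 0.001, 0.01) and
2000-iteration chains (1000 burn-in, thinning 2) — chain lengths chosen so
five replicates of either protocol complete in minutes on one core while
posterior means of the variance shares are stable to well under the
tolerances being checked.  Full-scale defaults (N=2000, M=103,638;
20,000/10,000/10 chains) remain the package defaults for the generator and
sampler.

## Known limitations

* Single-site Gibbs explores highly collinear column blocks slowly; PIPs
  dilute across near-duplicate columns (the variance partition is robust to
  this, individual-column inference is not).
* The Gaussian likelihood is not robust to phenotype outliers, and binary
  traits are not modelled.
* The realized-variance partition attributes shared signal between
  correlated groups (e.g. SNPs coupled to probes) according to the
  posterior's allocation; with strongly correlated groups the split is
  data-dependent and its posterior spread widens.
* Hyperparameter-scale variance shares (`sigma_g^2` normalization) are not
  reported for the reason given above; users wanting them can compute them
  from the stored chain.
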