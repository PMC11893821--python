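# Methods

`cqbatch` corrects batch effects in microbiome OTU count tables in two
stages: a negative-binomial stage that removes *systematic* effects
(per-batch mean shifts), and a zero-inflated composite-quantile-regression
stage that aligns the remaining *nonsystematic* distributional distortions
(batch-specific dispersion and zero-rate differences) to a data-driven
reference batch.

## Model

Let Y_ijg be the count of OTU j in sample i of batch g, N_i the sample's
total library size, X_i its covariate vector.

**Stage 1 (systematic effects).** Nonzero counts are modelled as negative
binomial,

    Y_ijg | Y_ijg > 0  ~  NB(mu_ijg, theta_jg),
    log mu_ijg = sigma_j + X_i' beta_j + gamma_jg + log N_i,
    Var = mu + theta * mu^2,

with gamma_jg a per-batch fixed effect under the sample-size-weighted
sum-to-zero constraint sum_g n_g gamma_jg = 0 (n_g = nonzero observations of
OTU j in batch g).  The constraint makes the model identifiable and defines
the "batch-free" mean as the weighted grand mean: log mu_ij* = log mu_ijg −
gamma_jg.  Per-batch dispersions are averaged, theta_j* = mean_g theta_jg.
Every nonzero count is then transported by quantile matching: its
midpoint-CDF level under the fitted zero-truncated NB(mu_ijg, theta_jg) is
re-read under the zero-truncated NB(mu_ij*, theta_j*), giving an integer.
Zeros pass through stage 1 untouched (the model conditions on Y > 0).

**Stage 2 (nonsystematic effects).**  A per-OTU logistic model estimates the
nonzero probability q_ij = expit(X_i' zeta + B_i' psi), with B_i the batch
indicator vector reference-coded against the selected reference batch.
Nonzero adjusted counts enter a composite quantile regression over the grid
tau_s = s/(k+1), s = 1..k (default k = 19, the 5th–95th percentiles):

    Q(tau_s | X_i, Y* > 0) = b(tau_s) + X_i' alpha + B_i' delta,

with one shared slope vector across the grid and per-tau intercepts,
minimising the summed check loss sum_s sum_i rho_{tau_s}(residual).  The
zero model and the positive-branch quantile function combine into the
zero-inflated quantile function

    Qc(tau) = 0                          tau <  1 − q_ij
    Qc(tau) = Q((tau − (1−q_ij))/q_ij)   tau >= 1 − q_ij.

Correction transports each sample onto the reference batch: the observed
value's level tau_obs under the sample's own-batch Qc is re-read under the
counterfactual reference context (same covariates, reference batch
indicators for both q and the quantile part), rounded half-to-even to a
non-negative integer.  Reference-batch samples pass through unchanged.

**Reference selection.**  Batches are screened for homogeneity: for every
batch pair and OTU, a Kruskal-Wallis test compares relative abundances
(zeros included); a batch's homogeneity is its fraction of non-significant
(p >= alpha, default 0.05) comparisons.  Batches at or above the median
homogeneity are shortlisted; among them the batch with the lowest Robust CV
(100 × MAD/median, no 1.4826 consistency factor; computed per OTU on the
batch's nonzero counts, aggregated by the median over OTUs) is selected.
Ties break toward the larger batch, then the lexicographically smaller
label.  A user-forced reference bypasses the screen.

## Estimation and numerical choices

- Stage-1 fits use joint maximum likelihood (statsmodels NB2) with log N_i
  as a fixed offset; non-convergence falls back to a Poisson fit with
  dispersion floored at 1e-4 and is flagged.  A design that is singular on
  the nonzero subset marks the OTU uncorrectable; it passes through both
  stages unchanged.
- Per-batch dispersions theta_jg are re-estimated after the mean fit by a
  one-dimensional MLE of the **zero-truncated** NB likelihood with the
  fitted means held fixed (bounded in [1e-4, 1e4]).  A plain moment match of
  squared residuals is biased low here because fitting happens on the
  nonzero subset; profiling the truncated likelihood removes that bias at
  negligible cost.
- Quantile matching uses the midpoint-CDF level (deterministic); the
  `stochastic_map` option draws the level uniformly within each count's
  probability interval (a randomised quantile residual, seeded) for
  distributional fidelity.  Levels are capped at 1 − 1e-10; beyond that cap
  the map returns the far-tail quantile.
- The composite quantile fit is solved exactly as a linear program (HiGHS
  interior point, dual simplex as fallback; convergence to the LP optimum,
  objective verified against grid-search oracles in tests).  Per-tau
  intercepts are monotone-rearranged (sorted), and predicted per-sample grid
  values are sorted again at prediction time, so quantile curves never
  cross.  `mode="per_tau"` fits every level independently instead (fully
  tau-indexed coefficients).
- Predicted positive quantiles interpolate linearly between grid levels,
  extrapolate as constants beyond the grid ends, and are floored at the
  OTU's smallest observed positive value.
- Zeros are transported at the midpoint of the zero mass, (1 − q)/2,
  deterministically; `stochastic_zeros` draws the level uniformly on
  (0, 1 − q) with a seed instead, trading determinism for distributional
  spread.  Inverting the positive branch uses the midpoint of the preimage
  interval; values below the branch minimum clamp to the first grid level.
- The zero model adds a small ridge penalty (lambda = 1e-4) on non-intercept
  terms and clamps probabilities to [1e-6, 1 − 1e-6] to survive
  quasi-separation in sparse OTUs; all-zero / all-nonzero OTUs get constant
  q at the clamp with a separation flag.
- OTUs with fewer nonzero observations than coefficients + grid size fall
  back to per-batch empirical quantiles (flagged); this also catches LP
  solver failures.
- Prevalence filtering (default: >= 3 nonzero samples in every batch) keeps
  the per-batch fits well-posed; filtered OTUs are re-attached to the output
  untouched and listed in the provenance as uncorrected.

## Evaluation suite

Four dissimilarities: Bray-Curtis, Manhattan and Canberra on raw counts
(Canberra skips double-zero coordinates; a `relative` switch rescales rows
first), and Aitchison as the Euclidean distance of CLR-transformed
compositions with pseudocount 0.5 (exposed as a flag).  One-factor PERMANOVA
R2 = SS_between / SS_total from the squared-distance decomposition, with a
permutation p-value (999 label permutations by default, seeded).  Classical
PCoA via eigendecomposition of the Gower-centred matrix (negative
eigenvalues dropped and counted).  Average silhouette over batch labels;
values near 0 after correction indicate well-mixed batches.

## Synthetic data

The generator mirrors the correction model: log-normal library sizes
(median 2e4 reads, log-sd 0.4), one standard-normal and one Bernoulli(0.5)
covariate, per-OTU baselines sigma_j ~ U(−7.5, −4), NB counts with per-batch
dispersion, and structural zeros imposed after sampling with probability
1 − q_ij from the logistic zero model (hurdle-like, so sampling and
structural zeros both occur).  Defaults put the overall zero fraction near
31%, the zero-inflation regime where quantile-based correction is most
stable; heavier inflation can be dialled in through `zero_intercept`.

Per-batch mean shifts are applied **per OTU**: `gamma_sd` (default 0.3)
scatters each OTU's batch effect around the batch-level value, and
`gamma_alternating` flips the sign on odd OTUs.  This matters: an
OTU-constant batch shift multiplies every count in the batch equally, is
absorbed into the observed library size, and is therefore both
compositionally invisible and unidentifiable under an offset model — it is
a sequencing-depth change, not a batch effect.  Recovery tests use the
alternating variant (exact truth); the study-shaped presets use scattered
effects (realistic).

Presets: `hivrc_like` (4 batches of 232/43/23/62 samples, 200 OTUs) and
`mouth_like` (7 batches of 43/49/56/79/89/88/91 samples, 200 OTUs) mirror
the shapes of a multi-study gut consortium and a multi-plate oral study;
both inject mean shifts, batch-specific dispersions and batch-specific
zero-rate shifts.  `null` has no batch effects.

What the generator does **not** emulate: phylogenetic correlation between
OTUs, compositional closure (counts are drawn independently given the
model), batch-confounded covariate distributions, and batch-specific
sequencing depth.  Passing tests therefore demonstrate correctness of the
estimators and transport under the stated generative model, not performance
on every real-data pathology.

## Problem sizes used in the checks

Oracle tests run on hand-sized instances; parameter recovery uses 2 batches
x 600 samples (~530 nonzero per batch) with 30 OTU replicates and asserts
the average absolute error (gamma within 0.1, pooled dispersion within 30%);
the end-to-end check runs the full `hivrc_like` preset (360 samples x 200
OTUs); null safety pairs 20 replicates of a 3x30-sample, 50-OTU null
configuration.

## Known limitations

- The composite fit assumes batch and covariate effects act as location
  shifts shared across quantile levels; strongly quantile-varying effects
  are better served by `mode="per_tau"`.
- Extreme quantiles are unstable for very sparse OTUs (few nonzero points);
  the empirical fallback and the prevalence filter bound, but do not
  eliminate, this.
- A reference batch that represents the other batches poorly propagates its
  idiosyncrasies to the whole table; the homogeneity screen mitigates this
  but cannot fix a study in which every batch is idiosyncratic.
- Confounding between batch and biology is out of scope: if a covariate is
  batch-confounded, removing the batch term removes biology with it.
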