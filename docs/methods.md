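# Methods

This note records the statistical models, the numerical choices behind the
implementation, and the design of the validation studies. Everything here is
implemented in `cottongp`; module names are given in parentheses.

## Data model (`cottongp.data_io`)

Genotypes are biallelic marker calls on inbred-candidate lines, stored
internally as **B-allele dosage** 0/1/2 (AA/AB/BB), with `NaN` for missing
calls. Marker QC retains markers with call rate **strictly greater than
0.85** and minor-allele frequency **strictly greater than 0.025**; the
removal counts are kept in a `FilterReport`. Missing calls are imputed per
marker by the mean dosage (default) or the modal dosage (ties broken toward
the lower dosage).

Phenotypes are line-level adjusted trait values carrying a `year` and an
`experiment` label; a line may be observed in several year/experiment
combinations. Pedigrees are three-column tables validated to be acyclic;
parents referenced but never declared are auto-created as unknown-parent
founders (with a warning).

## Relationship matrices (`cottongp.relatedness`)

**Genomic (G).** VanRaden Method-1 with per-marker standardization:

    G_ik = (1/p) * sum_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j))

with `p_j` the counted-allele frequency. By default `p_j` is estimated from
the data; `compute_grm(..., allele_freq=...)` accepts base-population (e.g.
founder) frequencies instead, which references G to that population — the
natural scale when comparing against a pedigree A matrix. Monomorphic
markers are an error (they divide by zero); run `filter_markers` first.

The dosage coding is fixed to 0/1/2 because the `2 p_j` centering term in
the formula presumes it; a −1/0/1 coding would make the expression
internally inconsistent.

**Pedigree (A).** The tabular method: founders get `A_ii = 1`,
`A_xi = 0.5 (A_si + A_di)` and `A_xx = 1 + 0.5 A_sd`. Ancestor traversal is
truncated at **5 generations** (individuals at the cut treated as founders),
which bounds the cost on deep selfing chains while capturing essentially all
the relationship signal used by the models.

## Linear Bayesian models (`cottongp.linear_bayes`)

All three samplers share one Gibbs engine over the observation-level model

    y = 1 beta0 + Z u [+ Z v] [+ W_exp alpha + W_yr gamma] + e

with a flat prior on the intercept, i.i.d. N(0, sigma2_alpha) /
N(0, sigma2_gamma) experiment and year effects, and N(0, sigma2_e)
residuals. Every variance component carries a **scaled inverse chi-squared
prior** with df = 5, in the convention

    p(sigma2) ∝ (sigma2)^-(df/2+1) exp(-S / (2 sigma2)),   draw = S / chi2(df).

Scales are derived from the observed phenotypic variance and an assumed
variance split (R² = 0.5 genomic by default; 0.4 genomic + 0.1 pedigree when
both kernels are present; 0.1 per environment factor): e.g. for BG-BLUP
`S0 = var(y)(1 - R²)(df + 2)` and `Sg = var(y) R² (df + 2) / mean(diag G)`.
A preset `ScaleSet` can be supplied for degenerate inputs (constant y).

**Factors with a single observed level are dropped from the model.** A
one-level factor is column-wise identical to the intercept; keeping it only
adds a prior-dominated variance draw to the heritability denominator. (In
a validation study this biased posterior h² from ≈0.5 down to ≈0.35.)

**BG-BLUP.** The genetic values are sampled through the eigen-factorization
`u = B b`, `B = V sqrt(Λ)` from `eigh(K)` over *all* lines (training and
held-out), with `b ~ N(0, sigma2 I)` updated coordinate-wise by a compiled
sweep. Held-out lines are thereby predicted **jointly** — their phenotypes
are simply treated as missing — and with clamped variances the posterior
mean of a test line's genetic value equals the Gaussian conditional mean
`sigma2_g G_ts (sigma2_g G_tt + sigma2_e I)^-1 (y - beta0)`, which the test
suite checks directly. Numerically null eigenvalues (below `1e-10 λ_max`)
are dropped; a mildly indefinite kernel is jittered once.

**Bayesian LASSO.** The unscaled hierarchy `beta_j ~ N(0, sigma_j²)`,
`sigma_j² ~ Exp(lambda²/2)` (marginally double-exponential with rate
lambda). Updates: `1/sigma_j² ~ InvGauss(lambda/|beta_j|, lambda²)` and
`lambda² ~ Gamma(shape + p, rate + sum sigma_j²/2)` with shape 1.1 and a
rate derived from the assumed variance split and MSx (the sum of per-marker
sample dosage variances on the training lines). `lambda²` can be held fixed
for oracle testing.

**Bayes C.** A spike-and-slab prior with common slab variance `sigma_b²`
(scaled-inv-chi² with scale `var(y) R² (df+2) / MSx`) and inclusion
probability `pi ~ Beta(p0 pi0, p0 (1 - pi0))` with p0 = 50, pi0 = 0.5. The
pair `(gamma_j, beta_j)` is updated jointly from the marginal Bayes factor;
posterior inclusion probabilities (PIPs) are reported per marker.

**Schedule.** The production default is 50 000 iterations, 10 000 burn-in,
thinning 20. `MCMCSettings.reduced()` (5 000 / 1 000 / 4) is the profile
used by the validation studies; chains of this length are ample for the
posterior means these studies compare. All samplers are bit-reproducible
given a seed: lines and observations are put in a canonical lexicographic
order before sampling.

**Heritability.** Per stored draw,

    h² = sigma2_g / (sigma2_g + sigma2_e + sigma2_alpha + sigma2_gamma)

(environment terms contribute zero when the model had none), summarized by
the posterior mean and the equal-tailed 95% credible interval. Whether the
pedigree variance belongs in the denominator is ambiguous in the literature;
`include_pedigree=True` adds it, and the default excludes it.

## BART (`cottongp.bart`)

A sum of M = 200 trees over the marker dosages plus one-hot year/experiment
columns (single-level factors dropped), fitted by backfitting MCMC. Tree
moves are grow / prune / change (0.4/0.4/0.2) accepted by
Metropolis–Hastings with the leaf values integrated out; split candidates
are one-value-versus-rest partitions of each covariate's observed values
(for 0/1/2 dosages this spans all binary splits). The depth prior is
`P(split at depth d) = alpha (1+d)^-beta` with (0.95, 2). Leaf means are
Gibbs-sampled with variance `sigma_mu² = 0.5/(k sqrt(M))`, k = 2; the
formula is read as a variance by default, with a `"sd"` option because both
readings coexist in the literature. The phenotype is scaled to [-0.5, 0.5];
the residual variance carries an inverse-chi-squared prior with df = 3
calibrated so the naive variance sits at its 0.90 prior quantile. Stored
per-line predictions evaluate the ensemble with environment columns at zero
(an environment-free genetic prediction, playing the role of a GEBV);
serialized tree snapshots support prediction at new covariate rows. There
is no pedigree variant of BART.

## Evaluation (`cottongp.evaluation`)

Prediction accuracy is the Pearson correlation between GEBVs and line-level
phenotypes (a line's mean over observations when it has several).

- **Scenario 1** — random k-fold cross-validation (default k = 5). Folds
  are a seeded uniform partition of the sorted line ids with sizes differing
  by at most one; 1385 lines give five folds of 277, or 27–28 lines per fold
  at k = 50.
- **Scenario 2** — forward-in-time: lines whose latest season precedes the
  cutoff year train the model; lines whose latest season equals the cutoff
  are the test population.
- **Scenario 3** — per-biparental-family prediction. Optionally the
  training set is restricted to lines whose *maximum* pedigree relationship
  with the family reaches a threshold (0.125 or 0.25 being typical);
  families with fewer than 3 phenotyped lines or an empty training set are
  marked skipped, never silently dropped.

## Simulator (`cottongp.simulate`)

Founder haplotypes are Bernoulli draws at per-marker frequencies
U(0.1, 0.9); biparental F1 crosses (random distinct parent pairs, so
founder reuse yields half-sib families) are advanced by single-seed selfing
to the configured generation (default 3 selfings, i.e. F4), each line
through its own chain, with all intermediates recorded in the pedigree.
Loci segregate independently — there is no recombination map, so family
structure alone carries the genomic signal; this is the main deliberate
simplification, adequate for validating relationship-based prediction but
not for LD-sensitive questions (marker density, fine-mapping).

Families are assigned round-robin to year cohorts (family turnover across
years), with experiments nested in years. Phenotypes follow the analysis
model: `y = mean + g + year + experiment + residual`, where g is an
additive QTL sum (optionally plus multiplicative epistatic pair terms) and
**each component is rescaled so the realised variance shares are exact**
(total variance 1). The generating truth (QTL indices, effects, true
breeding values, shares) is stored per trait.

## Validation-study designs

The desk-scale study conditions below were fixed before the studies were
run; they are choices of this package, not published values.

- **Fold arithmetic** uses 1385 ids, matching the published worked example
  (5 x 277; 35 folds of 28 and 15 of 27 at k = 50).
- **Sampler oracles**: the single-marker LASSO posterior is compared with
  2-D quadrature over (beta, sigma2_e) after integrating the flat-prior
  intercept analytically, within 3 batch-mean Monte-Carlo SEs; BG-BLUP with
  clamped variances is compared with the mixed-model-equation solution
  (correlation > 0.999 observed ≈ 0.99995).
- **h² recovery** uses a diverse non-inbred panel — 80 founders, 100 F1
  families x 4 offspring (n = 400), 1000 markers, 300 QTL, no environment
  terms — where mean diag(G) ≈ 1 and the h² formula is well calibrated.
  20 replicates at h² = 0.5 give a mean posterior h² ≈ 0.51–0.52.
- **Accuracy bound**: on the same panel at h² ∈ {0.25, 0.36, 0.5}, CV
  accuracy stays below sqrt(h²) + 2 SE, the theoretical ceiling for
  phenotype-referenced accuracy.
- **Bayes C calibration**: on a null trait the mean PIP must track the
  posterior mean of pi (both ≈ 0.45 observed); a single QTL explaining 30%
  of variance at the most informative marker attains PIP ≈ 1.
- **Pedigree gain** uses a *sparse-marker* design — 150 genotyped loci, all
  200 causal loci unobserved, strong family structure (30 families x 10 at
  F3) — because pedigree information complements G exactly when G is a
  noisy kinship estimate. Over 10 replicates the genomic+pedigree model
  gains ≈ 0.03–0.05 CV accuracy over genomic-only.
- **Relatedness mechanics**: textbook A values (0.5 parent–offspring, 0.25
  half-sib, 1.5 selfed diagonal) are exact; on gene-dropped data with
  explicit full-sib / half-sib / unrelated classes, class means of G
  (referenced to founder frequencies) match A within 0.05.
- **Scenario ordering**: with year effects (share 0.15) and family
  turnover, forward-in-time accuracy is distinctly below random-CV accuracy
  (≈ 0.30 vs ≈ 0.41 over 10 replicates), the expected ordering because the
  newest season consists of new families without phenotyped relatives.

`scripts/acceptance.py --seed <int> --out <path>` reruns all of these
studies from a single base seed and writes the quantities above as JSON.

## Numerical notes

- Variance draws are floored at 1e-10 to avoid degeneracy in pathological
  conditionals.
- The coordinate Gibbs sweeps (`cottongp._gibbs`) are numba-compiled and
  operate on Fortran-ordered design blocks; the first call in a session
  pays the JIT compilation cost.
- All derived seeds stay below 2^31.
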