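# Methods

This note documents the models, algorithms and numerical choices behind
`stemnsc`, and what its synthetic studies do and do not establish.

## The quantitative-genetic model

Replicated trait observations on a panel of inbred lines are modelled as

    y_ir = mu + a_i + d_i + eps_ir,        r = 1..m_i replicates of line i
    a ~ MVN(0, sigma2_a K)                 additive values
    d ~ MVN(0, sigma2_na I)                non-additive line effects
    eps_ir ~ family(0, sigma_e,i)          Gaussian or Student-t errors

`K` is the genomic relationship matrix `Zc Zc' / (2 Σ p_j (1 − p_j))` with
`Zc` the dosage matrix centred at twice the allele frequency; monomorphic
SNPs are excluded from the denominator and missing dosages mean-imputed.
Line-specific error variances are shrunk hierarchically:
`sigma2_e,i ~ InvGamma(nu_l/2, nu_l * sigma2_e0 / 2)` around a common scale
`sigma2_e0`, with `nu_l = 2` pseudo-replicates of shrinkage by default:
light pooling that keeps the estimates proper at two replicates per line
while preserving the between-line dispersion signal — the line CV
(`sigma_e,i / |line mean_i|`) is itself a trait of interest here, and heavy
pooling would flatten exactly the heterogeneity being studied (it also
masks the characteristic inflation of the error variance at small
replicate numbers, where shrunken genetic variance is reabsorbed as
apparent noise). Per posterior draw,

    h2 = sigma2_a / (sigma2_a + sigma2_na + mean_i sigma2_e,i)
    H2 = (sigma2_a + sigma2_na) / (same denominator)

so `0 ≤ h2 ≤ H2 ≤ 1` holds draw by draw; for Student-t errors the error
variance term uses scale² · nu/(nu−2). The line CV is reported as the
posterior mean of `sigma_e,i/|mu + a_i + d_i|` and flagged undefined when
the line mean is within 1e-8 of zero.

Priors: half-t(3, 2·SD(y)) on every standard deviation, Normal(mean(y),
(10·SD(y))²) on the intercept, Exp(0.1) on nu − 2 for the Student-t degrees
of freedom. The bivariate model (below) uses inverse-Wishart(4,
diag(empirical variance)/10) on its two covariance matrices; the first two
choices follow common weakly-informative practice, the IW scale was chosen
weak enough that a trait paired with an exact copy of itself recovers a
genetic correlation above 0.99 rather than being shrunk away.

### Sampler

All updates are Metropolis-within-Gibbs with the conditioning chosen to
avoid the two classic pathologies of variance-component samplers:

* the additive and non-additive effects enter only through their sum
  `u = a + d`, whose prior covariance `sigma2_a K + sigma2_na I` is diagonal
  in K's eigenbasis; `(sigma2_a, sigma2_na)` are drawn from their
  *u-marginalised* conditional (the precision-weighted line means are
  MVN(mu, sigma2_a K + sigma2_na I + diag(1/c_i))) by adaptive random-walk
  Metropolis on the log scale, plus a deterministic exchange proposal
  `(sigma2_a, sigma2_na) -> (sigma2_na, sigma2_a)` that crosses the ridge
  these two components share when realised relationships are close to
  identity. `u` is redrawn immediately afterwards (valid partially
  collapsed ordering), and `(a, d)` are recovered exactly from their
  Gaussian conditional given `u` when a draw is recorded;
* the intercept is drawn from its u-marginal (one extra triangular solve on
  the Cholesky factor already computed for `u`), removing the strong
  `mu`–`mean(u)` coupling;
* the common error scale `sigma2_e0` is updated with the line variances
  integrated out (their inverse-gamma marginal), then the line variances
  are redrawn conjugately;
* Student-t errors use the standard Gamma scale-mixture weights, and nu
  gets a random-walk Metropolis step on log(nu − 2).

Proposal covariances adapt towards ~30% acceptance during warmup only
(Welford running covariance, classic adaptive Metropolis scaling 2.4²/d)
and are frozen before sampling, so the kept draws target the exact
posterior. Without the marginalised updates the effective sample size for
h2 was ~10–80 at the study's panel sizes; with them it is ~200–1000.

Convergence is gated on split-Rhat < 1.05 (arviz rank-normalised, chains
split in half so single-chain runs are still diagnosed) for `mu`,
`sigma2_a`, `sigma2_e_mean` and `h2`. `sigma2_na` is reported but not
gated: its posterior often concentrates at the zero boundary, where any
sampler mixes slowly in a way that does not affect the gated parameters.

### Bivariate fits

Trait pairs are modelled as `y_ir = mu + a_i + eps_ir` with
`A ~ MVN(0, Sigma_g ⊗ K)` and residual pairs sharing a 2×2 `Sigma_e`
(Gaussian errors only; the univariate Student-t option exists to check
robustness of single-trait estimates). There is no separate bivariate
non-additive term: with near-identity realised relationships it is almost
perfectly aliased with the additive term and only degrades mixing, so
line-level genetic covariance is absorbed into `Sigma_g` — `r_g` is the
line-level genetic correlation. For balanced data the additive values are
collapsed analytically (eigenbasis line means are independent 2-vectors
with covariance `s_j Sigma_g + Sigma_e/m`) and the six covariance
parameters are sampled by adaptive Metropolis on (log-variance,
atanh-correlation) coordinates; unbalanced data fall back to a conditional
inverse-Wishart Gibbs scheme. Correlations are reported as (lower, point,
upper) equal-tailed credible triplets, 90% by default. Multi-trait
correlation matrices are assembled pairwise, matching how such tables are
usually presented and keeping runtimes at desk scale.

## The replicate-size study

`run_design_study` refits the model on within-line subsamples of exactly RS
replicates (drawn uniformly without replacement — mimicking having run a
smaller experiment, not a bootstrap) for RS ∈ {2, 5, 10, 15} by default.
Per draw it records accuracy (Pearson correlation of per-line estimates
against the full-data fit) for line means, GEBVs and line CVs; accuracy of
the pairwise genetic-correlation vector when ≥3 trait pairs exist; and
relative deviation `(sub − full)/full` for the variance components and h2.
The full-data reference fit runs with twice the per-chain samples of the
subsample refits. Fits failing the split-Rhat gate are logged and excluded
from aggregation, per failing fit rather than per draw. The default number
of subsample draws is 20; the shipped tests and acceptance script use 6–10
draws and 2 chains × (300 warmup + 500 samples) per refit to keep the
hundreds of refits at desk scale — medians and quartiles, not tail
quantiles, are the reported statistics, and they are stable at that size.

The replicate requirement for a parameter treats each subsample draw as
one experiment of size RS: a draw's score is the fraction of lines whose
estimate lies within [full/1.5, full×1.5] of the full-data estimate, and
the requirement is the smallest RS whose median draw brings at least 90% of
lines into the band — "the estimate comes within 1.5×" read as holding for
essentially all lines (a per-line median-over-draws variant is available,
but it averages away exactly the sampling noise the criterion is about).
The same rule applied to line means and line CVs yields the "dispersion
needs about twice the replication of the mean" comparison; on the default
synthetic study the line mean qualifies at RS 2 and the line CV at RS 10,
and the ordering is insensitive to the line-fraction threshold anywhere
above ~0.75.

## Synthetic data: what it emulates, what it does not

* **Genotypes** — dosages Binomial(2, p) under Hardy–Weinberg with uniform
  allele frequencies, 400 SNPs by default: a deliberately structure-free
  stand-in for a dense array at desk scale. No linkage disequilibrium and
  no subpopulation structure (out of scope), which matters: realised
  relationships stay close to identity, so the additive/non-additive split
  is weakly identified at 36 lines even though the total genetic variance
  (H2) is well estimated. Recovery of h2 itself is therefore tested at 200
  lines, where the split separates. Real diversity panels, with their
  strong structure, identify the split better at equal panel size.
* **Phenotypes** — the generator mirrors the fitted model by construction
  (the true data-generating process behind any real trial is unknown):
  SNP effects scaled so expected additive variance equals the target,
  exchangeable-or-matrix trait correlations applied to additive and
  non-additive effects alike, Gaussian or variance-matched Student-t(4)
  errors, and LogNormal(0, line_cv_spread) per-line error-scale
  multipliers. The design-study condition uses line_cv_spread = 0.5
  (~2.7-fold CV range across the central 90% of lines): line dispersion is
  treated in this workflow as a heritable trait needing ~10 replicates,
  which presupposes real heterogeneity; near-homogeneous CVs would make
  the 1.5× band criterion trivially passable at any RS.
* **Spectra** — Gaussian absorption bands per constituent plus a
  structural-matrix component with mass fraction 1 − (starch + sucrose),
  multiplied by LogNormal scatter and offset by a linear baseline in the
  normalised grid coordinate, with i.i.d. noise. The matrix term is
  essential, not cosmetic: without a dominant background the SNV step
  removes the absolute concentration scale entirely (closure), and ground
  stem tissue is in fact mostly structural matter. Starch spans
  0.02–0.35 w/w and sucrose 0.01–0.12, so the sucrose model is genuinely
  weaker — reproducing the qualitative R² ordering seen in real stem NSC
  calibrations. Wet-chemistry error (sd 0.006 w/w) was set so the
  reference-method uncertainty and RMSEP are comparable, the regime a
  well-built calibration operates in. No instrument physics beyond this
  linear-mixture model.

## NIRS calibration workflow

Pretreatment is fixed-order — restrict to 4000–9000 cm⁻¹, SNV (n−1
denominator), first-derivative Savitzky–Golay (25-point window, quadratic
polynomial, derivative scaled per cm⁻¹, half-window edges dropped rather
than extrapolated) — and recorded on the spectra; a model refuses input
whose pretreatment chain or grid differs from its training data.
Kennard–Stone (Euclidean distances in the pretreated space, ties to the
lowest index) splits 434 samples into 300 calibration + 134 validation.
"Full cross-validation" is leave-one-out; because P'W is upper triangular
in NIPALS, a single kmax-component fit per left-out sample yields the
predictions for every smaller component count by coefficient truncation
(verified against naive refits in the tests). The one-pass outlier rule
flags calibration samples whose cross-validated residual exceeds 2× the
initial model's RMSECV — for PLS-2, on either response. The final model is
refit without outliers and evaluated once on the untouched validation set
(a permutation test in the suite verifies no parameter depends on
validation responses). R² is 1 − SSE/SST about the evaluated set's mean
(squared Pearson available by flag); reference uncertainty is twice the
average within-sample SD of technical replicates, which for triplicates
underestimates 2·tau by the c4(3) ≈ 0.886 bias factor of the sample SD —
inherited from the estimator's standard definition, not corrected.
Component counts are user-set; a first-local-minimum-of-RMSECV helper
supports the choice (the synthetic study selects 3: two constituents plus
the curvature the SNV normalisation introduces), but the analyst inspecting
the curve has the final word.

## Trait formulas and contrast selection

The remobilisation index defaults to the mass-balance form
`100 × (TNC_hd·STM_hd − TNC_mt·STM_mt)/(TNC_hd·STM_hd)`; the variant using
the heading stem weight in both numerator terms is available behind
`as_printed=True`. Both are exposed because the two definitions circulate
and they agree exactly only when stem weight is unchanged between
samplings; negative values (net re-accumulation) are legal output. Maturity
groups split growth duration at <120 / 120–129 / ≥130 days. Contrast
selection standardises the traits, takes PCA on the correlation scale,
cuts complete- and average-linkage Euclidean trees at `n_clusters`, and
greedily maximises the minimum pairwise PC1–PC2 distance while preferring
joint clusters (consistent across both trees) not yet represented; ties
break to the lowest index, making the selection deterministic. The greedy
maximin is within the usual 2-approximation of the exhaustive optimum and
matches it on well-separated clusters (tested against brute force).

## Determinism

Every generator and sampler consumes an explicit integer seed;
`numpy.random.SeedSequence` derives stage and chain seeds, so pipelines
rerun byte-identically and the subsampling study is reproducible given the
(data seed, subsample seed, MCMC seed) triple.

## Known limitations

* The additive/non-additive decomposition is only as identifiable as the
  spread of realised relationships; h2 point estimates at very small panels
  are strongly prior-influenced (H2 is not).
* The bivariate model omits a separate non-additive covariance and a
  Student-t option.
* The spectra model is linear-mixture only — no wavelength-dependent
  scatter, temperature effects or water-band interference.
* Leave-one-out is the only cross-validation scheme; no venetian-blind or
  grouped CV.
* `run_design_study` assumes every line keeps at least RS replicates and a
  balanced bivariate layout for the fast path.
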