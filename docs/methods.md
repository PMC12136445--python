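# Methods

This note documents the statistical model, the numerical choices, what
the synthetic-data generators do and do not emulate, and the design
decisions made where more than one reasonable choice existed.

## Model and fitting

For a given species, the null ("strain") model for the host trait is

    E[f(y_i)] = X_i alpha + b_i,     b ~ N(0, tau * Psi)

with f the logit link for binary traits or the identity link for
quantitative traits.  `Psi` is the n-by-n genetic relatedness matrix
computed as 1 minus the Manhattan distance between binary gene
presence/absence profiles, normalized by the number of genes so that
relatedness lies in [0, 1].  Normalization matters: with unnormalized
distances the scale of `tau` would depend on pangenome size and values
would not be comparable across species.

`1 - normalized Manhattan distance` is not guaranteed positive
semidefinite.  Before fitting, the smallest eigenvalue is checked and, if
negative, a minimal diagonal ridge `delta = -lambda_min + 1e-6` is added
and recorded (`RelatednessMatrix.ridge`).  The GRM is used on its raw
scale (no centering or scaling) for model fitting; principal components,
where needed, are computed from the double-centered matrix (classical
principal coordinates) with a deterministic sign convention (the
largest-magnitude loading in each component is positive).

Fitting uses penalized quasi-likelihood: the GLMM is linearized to a
working linear mixed model with working response
`Ytil = eta + (y - mu)/W`, `W = mu(1 - mu)` for the logit link, and the
variance components are updated by average-information REML.  For binary
traits the residual term is absorbed into the PQL working variance (no
free dispersion parameter, `V = W^-1 + tau Psi`), matching the
GMMAT/SAIGE formulation; `sigma2` is a free parameter only for the
identity link (`V = sigma2 I + tau Psi`).

Numerical choices:

- Initialization: `alpha` from a plain (ridge-stabilized) IRLS GLM fit,
  `b = 0`, `tau0 = 0.5 var(working residuals) / mean diag(Psi)` (identity
  link: total variance split evenly between `tau` and `sigma2`).
- One AI-REML update of the variance components per outer PQL iteration;
  convergence when the maximum relative change in `(alpha, tau, sigma2)`
  is below 1e-4 (default), at most 50 outer iterations.  Non-convergence
  is flagged on the results object and warned about, never raised.
- Boundary handling: a Newton step that would take `tau` negative is
  step-halved toward the boundary; `tau < 1e-6` with a negative REML
  score is reported as exactly 0.
- All solves are dense Cholesky factorizations (n is hundreds here); the
  symmetric inverse of V is formed once per iteration and the projection
  `P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1` is applied through cached
  factors, never formed densely.
- With `Psi = I` and identity link, `tau` and `sigma2` are identified
  only through their sum; the fit converges to a split determined by the
  initialization and flags ill-conditioning of the AI matrix.

## Structure (tau) test

`T = mean(b_i^2)` summarizes the trait signal absorbed by the random
effects.  Significance comes from permuting the trait B times (default
1000 for analyses, 100 inside simulation harnesses), refitting the full
model per permutation, and

    p = (1 + #{T_perm >= T_obs}) / (B + 1).

Choices: only `y` is permuted, leaving covariates attached to samples —
this also breaks any y–covariate association, which is documented rather
than "fixed".  The add-one correction keeps p strictly positive; ties
count as exceedances (conservative).  Because the variance-component
estimate lives on a boundary, `tau_hat = 0` (hence `T = 0`) occurs in
roughly half of null fits; the permutation p-value then equals 1.  The
p-value distribution under exchangeable nulls is therefore conservative
(stochastically larger than uniform) with an atom at 1, not exactly
uniform; the tests check the one-sided property (no anti-conservatism)
and the nominal-level rejection rate.  A training-set AUC of the fitted
linear predictor is reported for binary traits; it is in-sample by
construction, because the random effects are per-host parameters that do
not generalize to unseen hosts.

## Gene (beta) test

Each gene is score-tested against the single null fit (no per-gene
refitting): `S = g~'(y - mu)` with the covariate-adjusted genotype
`g~ = g - X (X'WX)^-1 X'W g`, exact variance `Var(S) = g'Pg`, and
`z = S / sqrt(Var(S))`.  For binary traits with `|z| > 2` (the published
SAIGE default trigger) the normal tail is replaced by a saddlepoint
approximation of the conditional distribution of S given the fitted
means: the cumulant generating function of a weighted sum of centered
Bernoullis, with `g~` rescaled so `K''(0)` equals the exact variance, the
saddlepoint solved by bracketed Brent iteration, and the tail given by
the Barndorff-Nielsen formula.  The two-sided p doubles the tail on the
observed side (both tails are evaluated at the observed score and the
smaller is taken, which selects the observed direction for any unimodal
score distribution); the score distribution under case/control imbalance
is skewed, so mirroring the score instead would misstate the far tail.

When the rescaled adjusted genotype is a lattice variable (all nonzero
entries integer multiples of a common step — which happens in synthetic
and degenerate inputs, not with real covariate-adjusted genotypes), the
lattice form of the correction is used: the saddlepoint is evaluated half
a step toward the mean and the `v` term uses Daniels' `(2/h) sinh(h
zeta/2) sqrt(K'')`; a tail containing only the extreme support point is
returned exactly.  Without this, tail probabilities at lattice points are
off by 20–50% relative to exact enumeration.

The effect estimate `beta_hat = S / Var(S)` is a one-step approximation
(the score test does not estimate beta); it supplies the sign for the
localFDR z-transform and a direction for users, and is documented as
approximate.  Quantitative traits use `S = g~'(y - eta)/sigma2` with no
saddlepoint correction (the Gaussian score is exact).  Constant genes and
non-positive variances are flagged untestable (p = 1), never raised, so a
batch over thousands of genes always completes.

The plain-GLM baseline (trait on gene plus covariates, Wald test, no
random effect) is fitted by the package's own ridge-stabilized IRLS for
batch speed; statsmodels is used as the independent cross-check in the
test suite.  Quasi-separation is detected (diverging predictor with
perfect classification) and answered with a penalized refit and a flag.

## Multiple testing (localFDR)

Gene families co-occur across strains, so per-gene statistics are highly
correlated and tail-area FDR methods are unreliable here.  Two-sided
p-values are mapped to signed z-values, `z = sign(beta) Phi^-1(1 - p/2)`.
(The alternative literal reading — rank-based quantiles of signed half
p-values — is noted but not used: rank transformation destroys the
N(0,1) null reference that the maximum-likelihood null fit requires.)
The marginal density is estimated by Poisson regression of histogram
counts (120 equal-width bins) on a natural cubic spline basis with 7
degrees of freedom — the canonical locfdr defaults — and the empirical
null N(mean, sd) by truncated-normal maximum likelihood on the z-values
between the 10th and 90th percentiles, pooled across species; `pi0` is
the in-window mass ratio.  localFDR values are clipped to [0, 1].
One-sided test families (structure, abundance) are adjusted with sign +1.
Default significance thresholds (strict `<`): 0.2 for gene tests, 0.1
for structure and abundance tests.  The null fit is per test family.

## Synthetic data

`simulate_tau_dataset` builds a pangenome of 400 "core" genes
(Bernoulli 0.8), 400 "accessory" genes (Bernoulli 0.2) and 200
strain-linked genes: a latent strain with prevalence 0.5 is drawn per
host, strain-linked genes are absent whenever the strain is absent and
otherwise present with per-gene probabilities drawn uniformly from an
interval chosen in closed form so the mean presence odds is 1.8 (center
0.6221, half-width 0.15; note the center is *not* the probability whose
odds are 1.8 — Jensen's inequality — so matching the stated mean odds
fixes the center slightly lower).  The trait is Bernoulli(0.5)
independent of everything (null protocol) or Bernoulli(strain_delta)
with `strain_delta = (1-strain)(1-theta) + strain*theta` (power
protocol, odds ratio theta/(1-theta)).  An age-like covariate
~ Normal(45, 15) is always included.

`simulate_beta_dataset` starts from a base relatedness matrix,
standardizes its first 10 principal components, and simulates 90 genes
per component with per-sample presence probability `Phi(PC_std)`, plus
100 unstructured genes (presence probabilities Uniform(0.2, 0.8)).  The
trait is 1 when the PC1 and PC2 loadings have opposite signs, tying it
nonlinearly to 180 structured genes; power protocols append 100 causal
genes with presence probability `(1-y)(1-theta) + y*theta`.  False
positive rates are computed over the 820 genes not simulated from PC1 or
PC2; power at the empirical threshold that holds the FPR on negative
genes at or below 0.05 per method.

At desk scale no observed species relatedness matrices exist, so the
base matrix comes from a generated pangenome with **two** independent
strain blocks (200 genes each): the trait rule consumes the signs of two
principal components, so a faithful base needs two genuine structure
axes — a single strain yields only one, leaving PC2 as noise.  The
resulting structure estimates vary widely across replicates (tau_hat
roughly 0–7), as they do across real species.  The harness accepts a
user-supplied relatedness matrix to reproduce the original
observed-GRM protocol exactly.

What a green simulation test does and does not establish: the generators
produce independent Bernoulli genes given the latent structure, with a
single (or two) clean strain axes and no gene-length, coverage or
detection noise.  Real pangenome calls have copy-number thresholds,
linkage beyond single strain blocks, and missingness correlated with
sequencing depth; calibration on these synthetic worlds demonstrates
correctness of the statistics, not robustness to profiling artifacts.

## Known limitations

- One variance component per species; no sparse-GRM or variance-ratio
  approximations (exact per-gene variances are affordable at n in the
  hundreds, which is the regime of within-species metagenomics).
- The permutation test refits the model B+1 times per species; B = 1000
  with n = 250 takes on the order of half a minute.
- The abundance test consumes a precomputed relative-abundance table and
  uses abundance untransformed (a log10 option exists, off by default);
  no compositional transforms.
- localFDR needs at least 200 pooled z-values for a stable density fit;
  single-species runs with few genes skip the adjustment with a note.
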