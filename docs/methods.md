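# Methods

## Problem and estimands

We observe a labeled block L = {(Yᵢ, fᵢ, Xᵢ)}ᵢ₌₁..ₙ and an unlabeled
block U = {(fᵢ, Xᵢ)}ᵢ₌ₙ₊₁..ₙ₊ₙ.  The prediction f comes from an
upstream model trained on data disjoint from both blocks; the package
never trains it.  The target θ is defined through an estimating
function ψ with E[ψ(Y, X; θ)] = 0:

| estimand | ψ(y, x; θ) | solver |
|---|---|---|
| mean | y − θ | sample mean |
| quantile(q) | 1{y ≤ θ} − q | inverted-CDF (type-1) empirical quantile |
| ols | x(y − xᵀθ) | least squares |
| logistic | x(y − expit(xᵀθ)) | Newton, score-norm tol 1e-8, ≤100 iters |

Sandwich variances are A⁻¹BA⁻ᵀ/n with A the mean negative score
Jacobian and B the mean outer product of scores (HC0; no small-sample
degrees-of-freedom correction, so intervals at n ≈ 100 run mildly
anti-conservative — a deliberate, documented convention).  The
quantile score is non-differentiable; A is a Gaussian-kernel density
estimate of the outcome at the fitted quantile with the Silverman
rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), giving the
familiar q(1−q)/(n·f̂(θ)²) variance.  Logistic outcomes must be coded
0/1; anything else is rejected rather than recoded.

## Benchmarks

- *oracle*: fit on true outcomes of the unlabeled rows (simulation
  only; requires truths retained on U).
- *naive*: fit on predictions of the unlabeled rows.
- *classic*: fit on labeled rows only.

## PostPI

A relationship model links truth to prediction on L.  Continuous: OLS
of Y on f, with residual scale √(RSS/(n−2)) and HC0 covariance of the
two coefficients.  Binary: calibration frequencies P(Y=1 | f-class).

`postpi_boot` (B = 100 by default, B ≥ 2 required): for each draw,
resample N unlabeled rows with replacement, simulate pseudo-outcomes
Ỹ = γ̂₀ + γ̂₁f + N(0, σ̂²) (Bernoulli from the calibration table for
binary), and refit the estimand.  Point estimate: coordinate-wise
median of draws (robust to skewed bootstrap distributions).  SE:
mean of per-draw sandwich SEs (`parametric`, default) or SD of the
draws (`nonparametric`).  Both reflect variability at the unlabeled
scale N with the relationship model held fixed, so the SE is scaled by
√(N/n) by default (`scale_se=False` disables), acknowledging that the
information is bounded by the labeled sample.  Draw b uses a stream
keyed by (seed, b), so enlarging B never reshuffles earlier draws.

`postpi_analytic` (linear regression only): the naive fit of f on X
over U is pushed through the relationship model — slopes scale by γ̂₁,
the intercept shifts by γ̂₀ — and the covariance combines the
relationship-model and naive-fit covariances by the delta method,
treating the two blocks as independent.

## PPI, PPI++, PSPA

All three solve the weighted rectified equation

  mean_L ψ(Y; θ) + W·[ mean_U ψ(f; θ) − mean_L ψ(f; θ) ] = 0

with W = I (PPI), W = λI (PPI++), W = diag(ω) (PSPA).  For the mean
this is closed form; for ols it is a linear solve; for logistic a
Newton iteration started at the classic fit; for the quantile the
left-continuous root of the weighted pseudo-CDF over the pooled
candidate grid — chosen so that W = 0 reduces *exactly* to the classic
inverted-CDF quantile.  The asymptotic covariance is

  A⁻¹ [ Cov_L(ψ_Y − Wψ_f)/n + W Cov_U(ψ_f) W / N ] A⁻ᵀ,

with A the Jacobian of the weighted equation (for the quantile,
kernel-density plug-ins per block).  Covariances are centered with
divisor n; at W = 0 the labeled mean score vanishes at the solution,
so the classic HC0 sandwich is recovered to machine precision.

Weights are estimated at a preliminary W = I solve from the labeled
cross-covariance C = Cov_L(ψ_Y, ψ_f) (symmetrised) and the prediction
score covariances B_f,L and B_f,U, with ρ = n/N:

- λ (PPI++): ratio of traces of A⁻¹C A⁻ᵀ and A⁻¹(B_f,L + ρB_f,U)A⁻ᵀ —
  the summed-coordinate asymptotic-variance minimiser.  An optional
  `target_coord` restricts both traces to one coordinate when a single
  coefficient is the inferential target.
- ω (PSPA): per-coordinate in score space, ω_j = C_jj / (B_f,L,jj +
  ρB_f,U,jj), where each coordinate's criterion is decoupled.

Both are clipped to [0, 1] by default (raw values retained in the fit's
intermediates); a flat criterion yields weight 0, the conservative
labeled-only end.  Forcing λ or ω to 0/1 reproduces classic/PPI
exactly — these reduction identities are tested at 1e-10.

## Synthetic-data generator

The generator emulates the semi-supervised workflow at the study
conditions used throughout the tests: covariates X1..X4 ~ N(0,1),

  Y = β₁X1 + ½X2² + ⅓X3³ + ¼X4² + ε,  ε ~ N(0, σ_Y²),

β₁ = 1, σ_Y = 4, and splits of 100 training / 100 labeled / 1000
unlabeled rows (`set_label` ∈ {training, labeled, unlabeled}).  The
nonlinear terms give a flexible smoother signal beyond the linear
projection; β₁ is the exact linear-regression coefficient on X1 and
the inferential target.  The smoother is an additive penalized-spline
fit: cubic B-spline basis per covariate (≈10 basis functions), an
unpenalised intercept + linear block, and a single penalty on the
spline block selected by generalized cross validation on a log-spaced
grid.  Leaving the linear null space unpenalised matters: a uniform
ridge shrinks the linear signal and systematically attenuates every
prediction-based method.  Binary mode thresholds the latent Y at its
sample median, fits a penalised logistic smoother (fixed penalty 1.0),
and stores class predictions thresholded at probability 0.5.

What the generator does *not* emulate: covariate shift between blocks,
miscalibrated or heteroscedastic predictions, non-Gaussian noise, and
dependence between rows.  Passing tests therefore demonstrate
correctness of the estimators under exchangeable blocks with a
homoscedastic DGP, not robustness to those violations.

## Replicated benchmark and observed behaviour

`run_benchmark` replicates: simulate → train smoother → predict → drop
training rows → fit benchmarks and methods → record the X1 estimate,
95% interval, coverage and width.  Replicate r uses a seed spawned
from the master seed by key, so runs are reproducible and
parallel-safe; failed fits are recorded and skipped.  The default
problem size for validation is 500 replicates with B = 100 bootstrap
draws (about 20 s on one CPU).

At these study conditions the predictions are weakly informative
(out-of-sample corr(f, Y) ≈ 0.3, since only 100 training rows face
noise SD 4), and the measured behaviour is:

- PPI, PPI++, PSPA: mean X1 estimate within Monte-Carlo error of 1;
  empirical non-coverage near the nominal 0.05; PPI++/PSPA intervals
  at or slightly below the classic width, PSPA's replicate variance no
  worse than classic's or PPI's.
- PPI's interval is ~5% *wider* than classic — the known behaviour of
  unit-weight rectification under weak predictions, and precisely the
  motivation for power tuning.
- PostPI is attenuated (mean X1 estimate ≈ 0.7).  This is intrinsic,
  not an implementation artifact: the corrected slope is γ̂₁ × (naive
  slope), and γ₁ ≈ Var(m)/(Var(m) + Var(δ)) < 1 whenever the
  prediction carries estimation error δ; an independent replication of
  the pipeline with a reference GAM implementation gives ≈ 0.66 under
  identical conditions, and even an oracle-form parametric predictor
  trained on 100 rows gives ≈ 0.8.  PostPI is unbiased only in
  prediction-rich regimes (large training data), which these study
  conditions deliberately are not.  The corresponding acceptance-style
  tests are left failing rather than retuned.

## Numerical conventions and edge cases

- Quantile ties break toward the smaller value (left-continuous CDF).
- Singular designs, Jacobians, or fewer labeled rows than parameters
  raise rank errors rather than producing silent pseudo-inverse fits.
- Constant predictions make the relationship model unidentifiable and
  raise a degenerate-predictor error.
- Missing values in referenced columns are hard errors; rows are never
  dropped or imputed silently.
- One user seed drives everything; derived streams use spawn keys, so
  results are bitwise-reproducible and insensitive to the number of
  bootstrap draws requested elsewhere.
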