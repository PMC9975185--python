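# Methods

## Model

Two standardized phenotypes $Y_1, Y_2$ are linked by reciprocal causal
paths $\delta_{12}$ ($Y_2 \to Y_1$) and $\delta_{21}$ ($Y_1 \to Y_2$).
Every SNP belongs to one of four components: $G_1$ (direct effect on $Y_1$
only), $G_2$ (on $Y_2$ only), $G_C$ (pleiotropic, direct effects on both)
and $G_0$ (null), with mixing proportions $\pi_1, \pi_2, \pi_C, \pi_0$.
Direct effects are normal, $\gamma_1 \sim N(0, \sigma_1^2)$,
$\gamma_2 \sim N(0, \sigma_2^2)$, and for pleiotropic SNPs bivariate normal
with variances $\sigma_{C1}^2, \sigma_{C2}^2$ and covariance
$\rho_{C1,C2}$.  Solving the structural equations gives joint effects
$\beta = [I - \Delta]^{-1}\Gamma$ with
$\Delta = \begin{pmatrix}0 & \delta_{12}\\ \delta_{21} & 0\end{pmatrix}$;
stationarity requires $|\delta_{12}\delta_{21}| < 1$ (both are constrained
to $(-1, 1)$).  Marginal effects absorb LD:
$\tau_k = \sum_i \rho_{ki}\beta_i$ over the SNPs tagged by $k$.

GWAS summary statistics enter as standardized marginal estimates
$\hat\tau = z/\sqrt{n}$ with sampling variance $1/n$.  Conditional on the
latent composition $\mathbb{N}_k$ of SNP $k$'s tagging set (how many
tagged SNPs fall in each component), $(\hat\tau_{1k}, \hat\tau_{2k})$ is
bivariate normal with mean zero; each non-null component contributes a
term proportional to $(\text{count}/N_k^*)\,\ell_k$ — where $\ell_k$ is
the LD score and $N_k^*$ the tagging-set size — divided by
$(1-\delta_{12}\delta_{21})^2$, plus noise floors $a_t + 1/n_t$ (variance
inflation from, e.g., population stratification, plus sampling noise) and
a cross-trait covariance bias $\rho_0$ (sample overlap).  The composition
prior is multinomial in the $\pi$'s.  The composite log-likelihood sums
the per-SNP log mixture densities over all K SNPs as if independent; LD
correlation between SNPs is repaired at the inference stage by the
sandwich variance.

Causal identification rests on trait-specific SNPs: a $G_1$ SNP reaches
$Y_2$ only through $\delta_{21}$, so its two marginal effects are
proportional, whereas pleiotropic SNPs have a free covariance.  When a
trait-specific component is nearly empty the corresponding causal path is
weakly identified — that is what the sub-model machinery addresses.

## Estimation

Generalized EM.  The E-step computes posterior responsibilities of the
enumerated compositions; the closed-form M-step for $(\pi_1,\pi_2,\pi_C)$
is the expected fraction of tagged slots per component (the complete-data
maximizer under the multinomial prior); the continuous block
($\sigma^2$'s, $\rho_{C1,C2}$, $\delta$'s, $a$'s, $\rho_0$) is updated by
Nelder–Mead ascent of the observed composite likelihood with the $\pi$'s
held fixed (ECM-style, preserving the monotone-CL guarantee).

Unconstrained coordinates: log for variances, proportions and inflation
terms; $\tanh$ for the causal effects; the pleiotropy covariance through
$\tanh$ of its correlation (Cauchy–Schwarz holds by construction);
$\rho_0$ scaled by $\sqrt{n_1 n_2}$ — its natural magnitude is $O(1/n)$,
and without the rescaling both Nelder–Mead steps and finite-difference
derivatives are wildly mis-sized for it.

Starting values are method-of-moments: proportions from the excess of
$|z|>2$ SNPs spread over the mean tag count; genetic variances from
LD-score-deflated second moments, split evenly between specific and
pleiotropic components; causal effects from crude ratio (Wald-type)
estimates over strongly associated SNPs; $\rho_0$ from the cross-trait
moment of null-looking SNPs.

Three safeguards address pathologies of the composite likelihood surface:

1. **Label-swap correction.**  Competing local optima exchange a trait's
   specific variance mass with the pleiotropic component (observed on
   roughly 1–2 of 8 replicates at K = 30,000).  At convergence, swapping
   the per-trait heritability masses is proposed, advanced three EM
   iterations, and adopted only if the CL improves by more than 0.5.
2. **Nesting rescue.**  Sub-models are fitted independently from their own
   moment starts (their scatter is what feeds the averaged-variance spread
   term), with a reduced budget (12 EM iterations, CL tolerance 0.05, no
   swap or null passes — they feed the averaging stage, which tolerates
   looser convergence); if a nested sub-model nevertheless ends clearly
   above the full model's CL — impossible at true optima — the full model
   is refit from that point.
3. **Null-preferring resolution of equivalent causal parameterizations.**
   For pleiotropic SNPs the joint-effect covariance is
   $B\,\Gamma_C\,B^\top$ with $B=[I-\Delta]^{-1}$: a causal path and the
   direct-effect covariance are exactly interchangeable, so in
   pleiotropy-dominated data the likelihood is flat (or nearly so) along
   that trade and the EM end point on the ridge is arbitrary.  After
   convergence, the $\delta=0$-compatible point is reconstructed in closed
   form ($\Gamma_0 = (I-\Delta_0)\,B\hat\Gamma B^\top (I-\Delta_0)^\top$),
   polished by a short EM with the path frozen, and adopted whenever its
   CL is within ``null_margin`` (default 1.0) of the unrestricted maximum.
   Identified causal effects sit far above this margin (tens to hundreds
   of CL units) and are never touched; indistinguishable ones are reported
   as zero rather than as an arbitrary ridge point.

All stages derive their randomness from the single configuration seed;
repeated runs are bit-for-bit identical.

### Truncation of the composition sum

Per-component causal counts are capped at ``c_max = 4`` and the total
non-null count at ``c_total = 3`` (both configurable), with the
multinomial prior renormalized over the retained set.  At the mixing
proportions of interest ($\pi \le 3\times10^{-3}$) the excluded mass is
below $10^{-6}$ and the composite likelihood changes by under $10^{-3}$
(measured at K = 30,000), while the likelihood cost drops 1.7x.  Setting
both caps at $N^*$ makes the enumeration exhaustive; the oracle tests do
exactly that.

### Convergence and numerical guards

EM stops when the CL gain drops below ``cl_tol`` (default $5\times10^{-3}$
absolute — the CL is of order $10^5$ at K = 30,000, and the inner
Nelder–Mead resolution makes much tighter absolute tolerances
meaningless) or after ``max_em_iter`` (45) iterations; each M-step allows
100 CL evaluations (adaptive simplex).  Degenerate densities are guarded
by a $10^{-12}$ variance jitter.  A conditional covariance that leaves
the positive-definite region is clamped to 0.999 of the Cauchy–Schwarz
bound and counted; a fit whose final clamp fraction exceeds 1% aborts.
Mixture terms are accumulated in linear space with a floor at
$e^{-745}$, which holds the log-sum-exp contract down to densities of
$e^{-700}$.

## Sandwich inference

$\widehat{\mathrm{var}}(\hat\theta) = \hat I^{-1}\hat J\hat I^{-1}$ with
$\hat I$ the negative central-difference Hessian of the CL and
$\hat J = \sum_k U_k \bar U_k^\top$, where $\bar U_k$ sums the scores of
all SNPs tagged by $k$ (restricted to analysis SNPs).  Derivatives use
symmetric differences with relative step $10^{-4}$ in the unconstrained
coordinates; the covariance maps back through the analytic Jacobian of
the transforms.  Because parameters sit on very different curvature
scales, $\hat I$ is inverted in correlation form (diagonal pre-scaling);
directions with vanishing curvature — parameters pinned against a
boundary, e.g. $a_t$ when the true inflation is zero — are dropped via a
pseudo-inverse and reported as not-available rather than contaminating
the rest.  A parameter whose eigen-loading on a near-flat direction of
the scaled sensitivity matrix exceeds 0.3 is likewise reported as
not-available: the sandwich marginal variance along a likelihood ridge is
arbitrary and would understate the real uncertainty.  Wald tests are
$\chi^2_1$ on estimate/SE.

## Model averaging

The five-model set fits the full model and the four sub-models with one
or two components absent (absent parameters pinned at zero and excluded
from the free-parameter count).  Composite-likelihood AIC,
$-2\,CL + 2\,\mathrm{tr}(\hat I^{-1}\hat J)$, computed on the identified
subspace, seeds Akaike weights; the weights are then optimized by
Nelder–Mead in softmax coordinates to maximize the CL of the averaged
parameter vector (2 restarts, 60 evaluations each in the pipeline; the
standalone function defaults to 5/80).  Averaged variances follow
$\bigl(\sum_s w_s\sqrt{\mathrm{var}_{j,s} +
(\hat\theta_{j,s}-\hat\theta_{j,ma})^2}\bigr)^2$ with zeros for absent
parameters.  The averaged model becomes the final model if its CL exceeds
the full model's, or if either trait's full-model specific heritability
($K\hat\pi_t\hat\sigma_t^2$) is below 0.05 while $\hat\pi_t$ is not
significant at $\alpha=0.05$ (a boundary-pinned proportion with
unavailable SE counts as not significant); otherwise the full model
stands.

## Genetic correlation

$r_g$ is the correlation of the two traits' total additive-genetic
values implied by the fitted parameters: numerator
$\pi_1\delta_{21}\sigma_1^2 + \pi_2\delta_{12}\sigma_2^2 +
\pi_C[\delta_{21}\sigma_{C1}^2 + \delta_{12}\sigma_{C2}^2 +
(1+\delta_{12}\delta_{21})\rho_{C1,C2}]$; denominator the geometric mean
of the two genetic variances
$\pi_1\sigma_1^2 + \pi_2\delta_{12}^2\sigma_2^2 +
\pi_C[\sigma_{C1}^2 + \delta_{12}^2\sigma_{C2}^2 +
2\delta_{12}\rho_{C1,C2}]$ (and the mirror image).  The
$2\delta\rho_{C1,C2}$ cross terms belong in the genetic variances — they
are the covariance of the direct and the mediated pleiotropic paths —
and the individual-level oracle confirms the resulting $r_g$.  Its
variance comes from a numerical delta method (central differences,
relative step $10^{-5}$) against the parameter covariance; for averaged
final estimates only the diagonal of the averaged variances is available,
so the delta method then ignores parameter correlations (a documented
approximation).

## Synthetic data

The generator reproduces the study conditions the estimator targets.
Defaults: K = 30,000 SNPs in AR-1 LD blocks of 50 with neighbor
correlation $r = 0.5$ and tagging threshold $r^2 \ge 0.01$ (so interior
SNPs tag 7 SNPs with $\ell \approx 1.67$); $n_1 = n_2 = 50{,}000$ fully
overlapping samples; $\pi$'s of $10^{-3}$ (high polygenicity, the
settings of the sub-model and model-averaging experiments) or $10^{-4}$
(low polygenicity); heritability contributions 0.3 / 0.3 / 0.1 for the
$Y_1$-specific, $Y_2$-specific and pleiotropic components, giving
per-SNP variances $h^2/(\pi M)$; pleiotropy correlation 0.1 (the
scenario's $\rho_{C1,C2}$ is a correlation — as a raw covariance it
would violate Cauchy–Schwarz by three orders of magnitude); causation
null $(0,0)$, uni-directional $(0.1, 0)$ or bi-directional
$(0.1, 0.05)$.

Causal counts are exact ($\mathrm{round}(\pi_h M)$, sampled without
replacement), and drawn effect vectors are rescaled so each component's
realized heritability — and, for the pleiotropic pair, the realized
(non-centered) correlation — hit their targets exactly.  This is the
summary-level analogue of simulators that rescale the residual to pin
realized heritability: with only ~30 causal SNPs per component at desk
scale, the realized correlation of an unpinned draw has a standard
deviation near 0.2, which would swamp replicate averages of the
pleiotropy-covariance estimate with generator noise rather than
estimator noise.

True marginals are $\tau = R\beta$ within blocks; estimation noise is
matrix-normal with row covariance $R$ and column covariance
$[[1/n_1 + a_1, \rho_0], [\rho_0, 1/n_2 + a_2]]$, where
$\rho_0 = \mathrm{overlap}\cdot\min(n_1,n_2)\,\rho_Y/(n_1 n_2)$ and
$\rho_Y$ is the phenotypic correlation implied by the scenario (residual
variances solved so both phenotypes have unit variance after the causal
feedback).

What the generator does not emulate: real LD (block AR-1 is a surrogate
with the right contract, not an emulation of empirical human LD);
non-normal effect-size distributions; MAF- or annotation-dependent
architectures; binary traits and case-control ascertainment; population
stratification beyond the scalar inflation terms.  Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to their violation.

The individual-level simulator (capped at 5,000 SNPs x 5,000 samples)
thresholds a latent block-multivariate normal into {0,1,2} genotypes
under Hardy–Weinberg at uniform MAFs, builds phenotypes from the
structural equations, and estimates marginals by per-SNP least squares.
It is the ground-truth oracle for the summary-level path and for the
genetic-correlation formula; thresholding attenuates the latent LD
slightly, so oracle comparisons use low- or no-LD scenarios.

## Problem sizes used in the test suite

Routine tests run the pipeline at reduced scale: the bi-directional
recovery check uses 3 replicates at K = 30,000; null calibration 100
replicates at K = 10,000 (full-model fit, which is what the Wald test
needs); sub-model robustness 5 replicates x 3 presets at K = 10,000;
the Monte-Carlo consistency check 20 random configurations x 4,000
draws.  `scripts/acceptance.py` recomputes the headline quantities at
10 replicates x K = 30,000 per scenario.

## Known limitations

* At desk scale (~30 causal SNPs per component) the pleiotropy
  covariance and the weaker causal path are noisy per replicate; only
  replicate averages are meaningful.
* In pleiotropy-only data at desk scale the estimator can *hallucinate*
  trait-specific components: with only ~10–30 pleiotropic effect pairs,
  their realized heterogeneity rewards splitting the single bivariate
  normal into sub-components coupled across traits by a spurious causal
  path, with CL gains (tens of units) that no information-criterion
  penalty recovers.  The null-preference pass removes the exactly
  likelihood-equivalent cases, but genuinely CL-preferred spurious paths
  remain, and their Wald tests can reject.  This overfitting gain is
  bounded in the number of causal SNPs while genuine causal information
  grows linearly with it, so the pathology is specific to small causal
  counts.
* The composite likelihood has genuine competing local optima; the swap
  correction removes the common mode but global optimality is not
  guaranteed.
* Sandwich standard errors are conservative, as expected under composite
  likelihood; boundary parameters (true $a_t = 0$, $\pi_t = 0$) get NA
  standard errors by design.
* The variance of $r_g$ for averaged final estimates ignores parameter
  correlations.
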