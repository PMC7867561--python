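# Methods

`fsdcm` implements a hierarchical Bayesian analysis of resting-state
effective connectivity in a two-node frontostriatal network (left
dorsolateral prefrontal cortex, LDLPFC; left striatum, LSTR), with the
severity of psychotic symptoms as the between-subject covariate of
interest. This note records the model, the estimation choices, and what the
synthetic validation does and does not establish.

## Neural model

Each region contains one excitatory (E) and one inhibitory (I) population.
Linearizing around a fixed point gives, per region r,

    dE_r/dt = s_E E_r - (1/8) e^{theta_IE,r} I_r
              + sum_{q != r} (1/8) e^{theta_EE,q->r} E_q + u_r
    dI_r/dt = s_I I_r + g_EI E_r

Four parameters are free, as log scale factors on fixed default strengths:
two between-region excitatory (glutamatergic) couplings E->E at +1/8 Hz,
and two within-region inhibitory (GABAergic) couplings I->E at -1/8 Hz.
The exponential map enforces the sign of each connection for any finite
theta, and gives `exp(theta)` the interpretation of a multiplicative gain
on the default strength (1 = default; >1 = stronger).

The remaining rate constants are fixed, not estimated: self-decays
`s_E = s_I = -0.5 Hz` and the E->I gain `g_EI = +0.5 Hz`. These values are
a declared modelling choice (they are not published quantities); they give
a well-damped oscillatory system at the prior mean, and every quantitative
claim made by this package is about parameter *recovery* under its own
generative model, never about matching subject-level estimates from data we
do not have.

## Observation model and predicted cross-spectra

Endogenous fluctuations u drive the excitatory states with a power-law
one-sided spectral density `g_u(f) = alpha_u f^-beta_u` (defaults:
`beta_u = 0.5`, `alpha_u` such that band-integrated power is 1 on
0.0078-0.1 Hz). The measured BOLD signal reads the excitatory states
through a canonical double-gamma hemodynamic response (peak 6 s, undershoot
16 s, ratio 1/6, kernel normalized to unit integral) plus white observation
noise of density `alpha_obs` (default 1.0, i.e. roughly 10% of signal band
power). With A the 4x4 Jacobian, B the input matrix and C the E-state
readout, the predicted cross-spectral density (CSD) on the analysis band is

    S(f) = |H(f)|^2 M(f) G_u(f) M(f)* + g_obs(f) I,
    M(f) = C (2 pi i f I - A)^{-1} B,

a 2x2 Hermitian positive-semidefinite matrix per frequency, evaluated on a
32-point grid spanning 0.0078-0.1 Hz. All densities are one-sided;
integrating a diagonal entry over the band gives band-limited variance.

## Data preparation

Region series (360 volumes, TR = 1 s in the study design) are prepared by
(i) least-squares removal of nuisance regressors (motion, white matter,
CSF) when supplied, (ii) projection onto the complement of a discrete-
cosine drift subspace below 0.0078 Hz (constant included; in-band gain
>= 0.95), and (iii) when starting from voxel matrices, summarization to a
principal eigenvariate, sign-aligned to the mean voxel series and scaled to
unit variance. Band restriction above 0.1 Hz is enforced at the
cross-spectrum stage, not by time-domain low-pass.

## Observed cross-spectra

The observed CSD is a multivariate autoregressive (VAR) estimate: a
VAR(8) fit to the demeaned series, with spectrum
`S(f) = 2 dt A(w)^{-1} Sigma_u A(w)^{-H}`. Two facts about this estimator
matter downstream:

* its 128 real features on the grid are a smooth transform of only
  8*4 + 3 = 35 estimated parameters, so they carry at most 35 degrees of
  freedom of information; and
* its sampling covariance is computable by the delta method from the VAR
  coefficient covariance and the Wishart distribution of `Sigma_u`
  (`estimate_csd(..., with_uncertainty=True)` attaches it).

AR smoothing biases the estimate where the spectrum is steepest — the
bottom edge of the band, where a 6-minute record contains fewer than three
cycles. Validation therefore distinguishes the estimator's interior-band
accuracy (within 25% of the analytic CSD on long records) from the known
band-edge bias.

## Subject-level inversion (variational Laplace)

Parameters `phi = (theta_1..4, ln alpha_u, ln alpha_obs, lambda)` get
Gaussian priors: theta ~ N(0, 1/16) per component (a mild prior around the
default strengths), log-amplitudes ~ N(log default, 1/4), and lambda — the
log precision of the residual data features — N(0, 1) on standardized
residuals. Spectral exponents stay at their defaults: amplitude and
exponent are nearly collinear over the 1.1-decade analysis band, and
estimating both destabilizes the fit without improving it.

A Gauss-Newton scheme maximizes the Laplace free energy
`F = log-joint + (p/2) ln 2pi - (1/2) ln det H` with step-halving (accepted
steps never decrease F), a step-norm trust region of 8, convergence at
|dF| < 0.01 for three consecutive steps, and at most 128 iterations. The
posterior covariance is the inverse curvature at the optimum, symmetrized
and eigenvalue-floored. Optional deterministic multistart
(`n_starts > 1`) guards against local optima; in simulation the default
single start reaches the same optimum.

Two weighting decisions, both consequences of fitting a *parametric
spectral estimate* rather than raw data:

* **Residual scale.** Residuals are divided per frequency by
  `sqrt(S11 S22)` of the observed CSD (the scale of spectral sampling
  error under Wishart statistics), so lambda applies homogeneously across
  the band. Two alternatives are implemented — standardization by the
  propagated per-feature sampling SD, and full whitening by the propagated
  sampling covariance on its numerical rank. Full whitening calibrates
  posterior spread best but shrinks point estimates hardest on 360-sample
  records, and in a 20-cohort simulation study it degraded group-level
  recovery; the Wishart scale is the default.
* **Effective degrees of freedom.** The likelihood is scaled by
  `35/128` (estimator parameters / feature count, `data_weight="auto"`):
  counting every grid feature as an independent observation would
  overstate the evidence several-fold and produce overconfident
  posteriors.

Explained variance of a fit is `100 (1 - ||obs - pred||^2 /
||obs - mean||^2)` over the stacked unique real features (S11, S22,
Re S12, Im S12); cohort diagnostics flag subjects under 10% but never drop
them — the group level down-weights them through their posterior
precision.

## Group level (PEB) and model comparison

The second level is a Bayesian linear model `theta_i = B' x_i + eta_i`,
`eta_i ~ N(0, diag(1/gamma_c))`, over the four connectivity parameters,
with design matrices of the nine candidate symptom models: a constant, one
symptom covariate (P1, P2, P3, P1+P2+P3, N1, N4, N6, or N1+N4+N6), and two
nuisance covariates (binary antipsychotic exposure; duration of untreated
psychosis, mean-imputed where missing), all covariates mean-centred. The
null model is the constant alone.

Rather than re-running the first level, the empirical-prior recursion is
carried out with Bayesian model reduction: for Gaussian priors and
posteriors, the subject's posterior and evidence under any replacement
(empirical) prior follow in closed form, which makes the objective in B
exactly quadratic at fixed gamma. Per-connection random-effect precisions
`gamma_c` are optimized coordinate-wise under a log-normal hyperprior with
mode 256 (= 16x the first-level prior precision; log-sd 2); effects B get a
design-scaled prior — variance of effect (j, c) equal to the first-level
prior variance of connection c divided by the mean square of regressor j —
so a full-strength regressor swing moves theta by about its prior SD and
evidences are comparable across designs of different size. The model free
energy adds the Laplace correction over (B, log gamma).

Model comparison: `ln BF` relative to the best model, posterior model
probabilities by softmax of free energies under a flat model prior (they
sum to 1 by construction; BF = 20 maps to PP = 20/21 ≈ 0.952). A
connection-wise effect probability is computed by model reduction at the
second level — pinning that effect's prior variance to ~0 and converting
the free-energy difference to a probability — together with the effect's
sign.

One behaviour worth knowing: the hierarchy removes the first-level prior
from each subject before regressing (otherwise the prior would be counted
twice), which *de-shrinks* imprecise subject means. With very precise
subjects the group mean equals the shared subject mean; with noisy ones the
de-shrunk values are noisier than the shrunken posterior means they come
from. That is the correct hierarchical treatment, and it is why group-level
precision, not single-subject accuracy, is the quantity this analysis
relies on.

## Synthetic cohorts

The generator emulates the study conditions: 19 subjects; integer PANSS-8
items within the observed per-item ranges; ~40% with no antipsychotic
exposure; DUP on the observed 1-72 month range with ~10% missing; true
connectivity `theta_i = B' x_i + N(0, 0.1^2)` built from the same centred
design the analysis uses, with default covariate effects +0.1 log-units per
total-positive point on the two inhibitory connections and -0.1 on the two
excitatory ones (the qualitative pattern the analysis is meant to detect:
symptom load strengthens within-region inhibition and weakens between-
region excitation); band-limited power-law fluctuations synthesized in the
frequency domain (band padded by 0.004 Hz so leakage cannot attenuate the
exact band-edge bins the model is compared on); exact zero-order-hold
integration of the linear system (matrix exponential + modal IIR filters);
hemodynamic convolution; decimation to TR; white observation noise. Every
stage is seeded and reproducible.

What the generator does **not** emulate: head motion and physiological
artefacts, scanner drifts and low-frequency confounds beyond a clean
power-law, spatial/voxel-level structure, non-linear hemodynamics, and any
mismatch between the assumed two-state model and real neural dynamics.
Passing recovery tests therefore validates the *inference machinery* under
its own assumptions — they say nothing about model adequacy for real fMRI.

## Validation results and their limits

* The analytic CSD agrees with Welch cross-spectra of long brute-force
  simulations (2^20 samples) within 25% per entry on the band.
* With cross-spectra carrying moderate sampling noise (10% of the Wishart
  scale, roughly a 100-segment estimate), the inverter recovers the four
  parameters with true-vs-posterior correlations >= 0.8 over 50 subjects
  drawn from the prior.
* At the study's own scale (6-minute records), single-subject recovery is
  information-limited — the slowest band frequency completes fewer than
  three cycles per record, and per-parameter correlations fall to
  ~0.1-0.4. This is a property of the data regime, not of the optimizer
  (which is exact on clean features), and it is precisely why the analysis
  is hierarchical.
* Over 20 simulated 19-subject cohorts, the group level recovers the
  generating effect signs on all four connections in ~75-95% of cohorts
  depending on the seed batch (~90% per connection), and Bayesian model
  comparison selects the generating covariate model more often than any
  alternative.

## Numerical choices

Frequency grid 32 points on [0.0078, 0.1] Hz; VAR order 8; inversion
tolerance 0.01 nats, max 128 iterations; PEB rounds max 16 at the same
tolerance; covariance floors at 1e-10 relative; simulation step 0.1 s with
burn-in 64 s; problem sizes in the recovery studies are 50 subjects and 20
cohorts. Degenerate inputs fail loudly: unstable Jacobians, non-PSD
observed spectra, rank-deficient designs and zero-variance tests raise
errors rather than propagate.

## Known limitations

Two regions and two populations per region are a deliberate minimal model;
the fixed rate constants are declared, not published values; the
explained-variance definition and the hemodynamic model are package
choices where the upstream description is silent; single-subject estimates
from 6-minute records should not be interpreted individually; and absolute
free energies depend on the package's own priors, so only free-energy
*differences* within one analysis are meaningful.
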