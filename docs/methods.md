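# Methods

## The model

`sdssm` implements three semisupervised deep state-space models (SDSSMs)
for daily greenhouse time series with a dense and a sparse observation
channel. The generative skeleton shared by all variants is a nonlinear
state-space model over days `t = 1..T` of one cultivation sequence:

    z_t | z_{t-1} ~ N( mu_z(z_{t-1}, u_t), diag sigma_z(z_{t-1}, u_t)^2 )
    x_t | z_t     ~ N( mu_x(z_t, s_t),     diag sigma_x(z_t, s_t)^2 )      (sugar, brix)
    y_t | z_t     ~ N( mu_y(z_t, r_t),     diag sigma_y(z_t, r_t)^2 )      (stem diameter, mm)

with `z_0 = 0`. The conditioning covariates are routed per variant:
`u_t` (climate and growth drivers) feeds the transition, `s_t` (CO2, solar
radiation, one-hot cultivation-step id) the sugar emission, and `r_t` is
empty by default (no action variables in this setting). All conditional
parameters come from conditioner networks: a trunk of fully connected +
ReLU (optionally batch-normalized) layers — with an LSTM first layer for
the networks that emit latent states, so the transition and recognition
can carry causal context — feeding two separate affine heads for the mean
and the log standard deviation (log-parameterized for positivity, clamped
to |log sigma| <= 7).

The three variants differ in the latent space:

* **cont** — one continuous Gaussian chain `z_t` (water content and growth
  mixed in a single vector state);
* **disc** — one categorical growth-stage chain, sampled through the
  Gumbel-Softmax relaxation (temperature `tau`, default 1.0) so discrete
  draws stay reparameterizable; its KL terms use the analytic categorical
  divergence of the underlying class probabilities;
* **2l** — both chains, a priori independent: `z_t` driven by climate
  (`u_t`), the stage chain `d_t` driven by the growth covariates (`v_t`,
  elapsed days and accumulated temperature); emissions read `z_t` only
  unless `emit_from_stage` is set.

## Inference and the objective

Recognition factorizes causally, `q(z_t | z_{t-1}, x_{1:t}, y_{1:t})`:
a causal LSTM encoder consumes the per-day observations and covariates and
a dense head combines its state with the sampled previous latent. Missing
sugar values are imputed inside recognition by the model's own imputation
distribution `q(x_t | ...)`; its conditioning is configurable:

* `instantaneous` — `q(x_t | y_t, s_t)`, the minimal form;
* `causal` (default) — `q(x_t | y_{1:t}, u_{1:t}, s_{1:t})` through a
  dedicated causal LSTM, because sugar content integrates past water
  stress and the dense-channel *history* is informative about it.

Per timestep the bound accumulates the reconstruction log-likelihoods of
both channels under a single reparameterized latent sample, minus
beta-weighted analytic KL terms between the recognition and prior
transitions. At timesteps with missing sugar, the observation is replaced
by a reparameterized draw from the imputation model and the bound gains
that model's entropy (the unlabeled bound); sequences with mixed masks
contribute both kinds of terms through one shared chain and reduce exactly
to the pure labeled/unlabeled bounds in the all-observed/all-missing
cases. The training loss is the negative sum of these bounds plus
`alpha * sum_observed -log q(x_t | ...)`, the regression term that lets
the imputation model learn from measured sugar (evaluated over observed
points; the bound itself carries no information about x values the model
never sees). Everything is optimized jointly by Adam on single-sample
reparameterized gradients with global-norm clipping.

Two optional behaviors matter in practice and are off in the strict
formulation but on in the package's flagship experiments:

* **`impute_recognition_x`** — condition the recognition encoder on the
  imputation mean at *every* timestep, observed or not (targets still use
  the measured values; any recognition distribution yields a valid lower
  bound). Without this, recognition learns to pass the observed sugar
  value through the latent state at measurement days and collapses to the
  static imputer whenever sugar is unavailable — a train/deployment
  mismatch.
* **emission noise floor** (`emission_min_log_std`, default ln 0.1 in
  standardized units) — measurement channels have a known precision;
  letting the modelled observation noise collapse toward zero gives that
  channel unbounded likelihood weight and freezes all other learning.
  This is the usual variance-floor safeguard from classical state-space
  fitting.

KL annealing raises beta linearly by a fixed increment per epoch from 0,
clamping at 1 (default increment 1e-4; short experiments scale the
increment so the ramp spans the run). Model selection keeps the epoch with
the lowest validation MAE of predicted sugar at observed points, on the
original brix scale.

### Supervised twins

The supervised (SV) baselines are the same architectures trained on the
*labeled dataset only*: each sequence is restricted to its measurement
days, so the chain steps over 3-day gaps and never touches unlabeled
records. With every mask entry equal to one, the mixed objective reduces
exactly to the labeled bound plus the regression term, so supervised mode
is a data restriction, not a different estimator.

### Prediction

`predict_sugar` runs sampled recognition sweeps, pushes each latent draw
through the sugar emission, and aggregates the per-sample means and
variances by the law of total variance; results are inverse-standardized
to brix. By default recognition is *not* conditioned on the observed test
sugar: conditioning on the value being scored is near-circular for a
reconstruction-style model (the supervised twin reaches 0.10 MAE that
way), so the deployment protocol imputes sugar everywhere. A
`use_observed_x` flag restores the conditioned variant for filtering-style
use.

## Verification against the exact linear oracle

With `n_hidden = 0` and the identity encoder every conditioner is affine,
so the model class contains linear-Gaussian state-space models exactly,
and the Kalman filter/smoother provides closed-form marginal likelihoods
and posteriors. The default verification system is

    z' = 0.7 z + 0.3 u + N(0, 0.5^2),  x = 0.8 z + N(0, 0.4^2),
    y = z + N(0, 0.2^2)

— deliberately observation-dominated with the *dense* channel the sharp
one, as stem diameter is in the real system. Two failure modes guided
this choice. First, when future observations carry much information about
the current state, the causal-filtering recognition family is inherently
loose (an 8% ELBO gap at the true parameters in one regime we measured),
so bound tightness would measure the regime rather than the inference
code. Second, when the *sparse* channel is the sharp one, the ELBO
develops a competitive "autoencoding" optimum that stores observation
noise in the state; its filtered means deviate systematically from the
true Kalman filter. With a sharp dense channel neither pathology has
room, and the recovery experiment (20 sequences, T = 30, 2000 full-batch
Adam steps at KL weight 1, staged learning-rate decay) lands within a few
percent of the exact log-likelihood with filtered means within a tenth of
a prior standard deviation of the Kalman filter, across seeds. Fitted
latents are identifiable only up to an invertible affine map (any
rescaling is absorbed by the transition and emissions), so posterior means
are compared to the Kalman filter after least-squares affine alignment.

The bound experiment evaluates 100 random affine recognition settings
(Monte-Carlo ELBO must not exceed the exact log-likelihood by more than 3
standard errors) and the exact-posterior setting, computed per sequence by
conditioning the joint Gaussian of states and observations — by the chain
rule the product of `p(z_t | z_{t-1}, all obs)` is the exact posterior, so
the sequential bound is tight there.

## The synthetic greenhouse

The generator emulates the structure of a tomato deficit-irrigation
trial: 16 beds x 3 cultivation steps x 83 daily records (late August to
mid November), with sugar measured every third day and stem diameter
daily. Climate: a seasonal cooling trend with AR(1) weather anomalies
(`26 -> 14` degC), solar radiation correlated with the temperature
anomaly, VPD derived from temperature, CO2 around 400 ppm; elapsed days
and accumulated temperature (exact running sum of daily temperature) as
growth covariates. Ground truth holds two plant states per sequence:

* water content `w_t` — AR(1) (persistence 0.85) pulled down by the VPD
  anomaly, replenished by scheduled irrigation pulses (period 7 days,
  phase varying by bed and step) and dominated by idiosyncratic noise
  (sd 0.35 vs a VPD coupling of 0.6), so climate covariates alone cannot
  reconstruct it;
* growth stage `g_t` — a monotone 3-stage chain switched by
  accumulated-temperature thresholds.

Stem diameter = growth trend (7 -> 10 mm over the season) + 0.6 `w_t` +
noise (0.5 mm — the effective noise of a daily average over intraday
shrink/swell cycles, not the raw sensor precision). Sugar = a per-stage
base level (5.4 / 6.4 / 7.3 brix) + 2.0 x a *sustained water deficit*
(an exponential moving average of `-w_t` with memory 0.9) + a persistent
bed-level offset (sd 0.15) + noise (0.25 brix), clipped to the observed
brix range [4.67, 10.73]. Making sugar respond to the stress *integral*
rather than the instantaneous state is the biologically motivated choice
(deficit irrigation works through sustained stress) and is also what
gives the data a genuinely temporal signal: the irreducible noise floor
for sugar is sigma_x * sqrt(2/pi) ~ 0.20 brix, reachable only by a model
that tracks the water history. A `label_dropout` option can thin the
measurement schedule to the ~50% coverage of the emulated field campaign
(about 380 labeled records per 9-bed training split); the default keeps
the full every-third-day schedule so the mask density is exactly
ceil(T/3)/T.

What the generator does **not** emulate: calibrated crop physiology (no
photosynthesis or transpiration model), real irrigation policy, sensor
drift, within-bed plant heterogeneity, or measurement-protocol artifacts
in the sugar readings. Passing tests on this data show the inference
machinery is correct and that the study design is reproduced — not that
the model would reach any particular accuracy on real cultivation data.

## Known limitation: the semisupervised margin

A deterministic twin of the architecture (the same LSTM encoder and heads
trained by plain masked MSE) learns the temporal sugar map on this data
(test MAE ~0.46-0.54 vs ~0.65 for a static imputer; a stacked-LSTM
baseline reaches ~0.38). The variational model largely does not: with the
dense-channel reconstruction term active the shared encoder is captured
by the stem-diameter likelihood and the sugar path plateaus at the
static-imputer level, and the unlabeled-step sugar reconstruction anchors
the emission to the imputation model. Removing the dense-channel term (an
ablation, not a supported mode) lets the same machinery learn the
temporal map — the limitation is the joint objective's optimization
landscape, not the architecture. As a consequence, after best-validation
selection the supervised twin is about as accurate as the semisupervised
model on this generator, and the semisupervised-minus-supervised test-MAE
margin is noise-dominated across simulated seasons: the package's
replicated comparison (`semisupervised_benefit_experiment`, 10 fresh
seasons, both twins selected on validation MAE) does **not** reproduce a
consistent semisupervised advantage at the problem sizes used here. The
experiment is reported as measured.

## Problem sizes and numerical choices

* Verification experiments: T = 5 (bound), T = 30 x 20 sequences x 2000
  steps (recovery); benefit experiment: 10 replicate seasons, continuous
  variant with z_dim 8, 64 hidden units, 200 epochs of full-sequence
  full-batch Adam (lr 2e-3, KL ramp spanning the run, alpha 1.0),
  validation every 5 epochs with 6-sample predictions. These sizes are the
  package's chosen study conditions for a single-workstation run.
* Default hyperparameters: hidden width 128 (conditioners), z_dim 8, K 5,
  Adam lr 1e-3, gradient clip 10, alpha 0.1, beta increment 1e-4/epoch,
  tau 1.0; He initialization for hidden layers with distribution heads at
  0.01x He scale so training starts from mu ~ 0, sigma ~ 1 and the first
  KL terms are well scaled.
* Batch normalization is available in dense trunks but off by default
  (small-batch statistics are noisy at these problem sizes); recurrent
  trunks never use it.
* Ties and degenerate inputs: zero-variance features standardize to zeros
  with a warning; constant targets make RAE/RSE undefined (NaN with a
  warning); rank-deficient latents return fewer principal components with
  a warning.
* One root seed is split into named streams (zlib.crc32, < 2^31) for
  initialization, shuffling, reparameterization noise and evaluation
  sampling, so every run is exactly reproducible.
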