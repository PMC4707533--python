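# Methods

## Task and stimulus model

A trial presents a single dot that jumps to a fresh position every
`dt_ms = 93.2` ms, for at most `max_dots = 25` positions (deadline
25 × 93.2 ≈ 2330 ms). Positions are i.i.d. draws from an isotropic 2-D
Gaussian with per-axis SD `sigma_stim = 70` px centred on one of two
targets at (±offset, 0) px; the offset is 10/25/40/55 px for difficulty
conditions D1 (hardest) to D4 (easiest). The coordinate frame has its
origin at the screen centre, x rightward, y downward. The task specifies
only horizontal target offsets, so both targets are placed on the centre
row; this vertical placement is an assumption of the package, not a datum.
A canonical session holds 200 trials per condition (100 per side, 800
total); the full stimulus set is generated once and participants differ
only in a random viewing order, which preserves the design feature that
every participant sees identical stimuli.

All 25 dot positions are generated up front even though a response
truncates viewing — the model consumes only the first t_d of them, which
matches an experiment whose stimuli are pre-generated.

## Decision model

The observer holds posterior beliefs g_t = (g_t(left), g_t(right)) that
the dot stream is generated around each target, starting from a prior
(`prior_left`, 1 − `prior_left`) and updating after each observation x_t:

    g_t(i) ∝ N(x_t | μ_i, sigma_stim² I) · g_{t−1}(i)^λ ,  renormalized,

with the stimulus generative densities serving as the observer's internal
models (the internal likelihood keeps the stimulus SD; sensory noise
corrupts the observation, it does not widen the likelihood). The leak
exponent λ (`discount`) is 1 for lossless accumulation and 0 for no
accumulation at all; the update is computed in log space, and with
mirror-symmetric targets it reduces to a 1-D log-odds random walk
l_t = λ·l_{t−1} − 2·offset·x_t / sigma_stim², which is what the vectorized
simulator iterates. The scalar reference path (`belief_update`,
`run_accumulation`) and the vectorized path (`simulate_responses_batch`)
are checked against each other exactly in the noise-free limit and
distributionally otherwise.

A decision is made the first time a belief reaches the confidence bound;
the decision step t_d (1-based dot count) converts to a reaction time
rt = t_d · dt_ms + NDT, where the non-decision time is log-normal with
parameters (`ndt_mu`, `ndt_sigma`) on the log-millisecond scale. Summaries
use the standard identities mode = exp(μ − σ²) and
sd = sqrt((exp(σ²) − 1)·exp(2μ + σ²)); `ndt_params_from_summary` inverts
them with a bracketed scalar root solve, which is needed to drive
simulations from published (mode, SD) pairs.

Input modes:

* `exact` — x_t is the trial's t-th dot position plus isotropic sensory
  noise of SD `sigma_s` px (exact input model, ExaM);
* `ddm_equivalent` — x_t is the constant true-target mean plus the same
  noise. The log-odds increments are then i.i.d. Gaussian with mean
  (μ_R−μ_L)ᵀ(μ_true−(μ_L+μ_R)/2)/sigma_stim² and variance
  ‖μ_R−μ_L‖²·sigma_s²/sigma_stim⁴, i.e. the machinery is a pure
  drift-diffusion model. Both closed forms are asserted empirically in the
  test suite.

### Bound variants

The time-varying bound is

    b(t) = b0 − s·(b0 − 0.5)·(t/t_max)^k ,

with initial bound b0 ∈ (0.5, 1], collapse fraction (`stretch`) s ∈ [0, 1]
and timing (`shape`) k > 0. This power-law family was chosen by the
package as the simplest form with all the required limit behaviours:
b(0) = b0; s = 0 keeps the bound fixed; s = 1 collapses it exactly to 0.5
at the deadline; k < 1 front-loads the collapse, k > 1 delays it; the bound
is monotone non-increasing and never falls below 0.5. `leaky` with λ = 1
and `collapsing` with s = 0 reduce bit-exactly to the `standard` variant
under shared seeds (a tested invariant).

### Lapses, timeouts, tie-breaks

With probability `lapse_p` a trial is a lapse: it times out with
probability `lapse_to_p`, otherwise the choice is a fair coin and the RT
uniform on (0, deadline]. Evidence-based trials time out when no belief
crosses the bound within 25 steps — the deadline applies to the decision
variable. An optional stricter rule (`deadline_on_total_rt`) additionally
times out decisions whose t_d · dt_ms + NDT exceeds the deadline; it is off
by default because the task's deadline is defined on the stimulus, and at
the reference parameter sets it changes outcome frequencies by under a
third of a percentage point. With two alternatives and a bound above 0.5 a
two-sided crossing is impossible; at exactly b = 0.5 the larger belief
wins and an exact tie is resolved by a fair coin. Beliefs are clamped to
[1e-12, 1 − 1e-12] before log transforms so extreme observations cannot
produce infinities; the clamp is far below any practically reachable bound.

## Inference: EP-ABC

The posterior over parameters is approximated per participant-condition
dataset by expectation propagation in a likelihood-free setting. Parameters
live on an unconstrained scale z with a standard-normal prior; element-wise
transforms implement constraints and priors:

| parameter    | transform            | implied prior            |
|--------------|-----------------------|--------------------------|
| `sigma_s`    | exp(log 50 + z)       | log-normal, median 50 px |
| `ndt_mu`     | 6.0 + 0.5·z           | normal (log-ms scale)    |
| `ndt_sigma`  | exp(log 0.35 + 0.7·z) | log-normal               |
| `bound`      | 0.5 + 0.5·Φ(z)        | uniform (0.5, 1)         |
| `prior_left` | Φ(z)                  | uniform (0, 1)           |
| `lapse_p`    | 0.3·Φ(z)              | uniform (0, 0.3)         |
| `lapse_to_p` | Φ(z)                  | uniform (0, 1)           |
| `discount`   | Φ(z)                  | uniform (0, 1)   (leaky) |
| `stretch`    | Φ(z)                  | uniform (0, 1) (collapsing) |
| `shape`      | exp(0.7·z)            | log-normal    (collapsing) |

These widths were chosen once to cover all plausible values for this task
(sensory noise up to several hundred px, non-decision times of roughly
100–1600 ms) while enforcing positivity and probability ranges; lapse rates
above 30% were considered implausible for trained observers. All transforms
are configurable per fit.

The approximation is prior × ∏ sites, one Gaussian factor per trial. A site
update draws proposals from the cavity (global ÷ site), simulates one
response per proposal, and accepts proposals whose response matches the
observed choice with |ΔRT| strictly below ε (`eps_ms`, default 46.6 ms —
half the dot duration); a timeout observation is matched by any simulated
timeout, since timeouts carry no RT. After at least `min_accepted = 300`
acceptances the global Gaussian is moment-matched to the accepted sample
and the site set to the ratio. Fits make `passes = 4` sweeps over the
trials. The per-site evidence contribution is log(acceptance rate) −
log(2ε) (the window normalizer; omitted for timeout data) plus the standard
EP log-partition correction, and the total log evidence is validated
against an exact quadrature oracle on a conjugate toy problem and against
brute-force rejection ABC on small behavioural datasets.

Three stabilizers matter at realistic dataset sizes, all tuned for
correctness of the fixed point rather than for any particular dataset:

* **moment debiasing** — the inverse of a 300-sample covariance
  overestimates precision by ≈(n−1)/(n−d−2); left uncorrected, this ~3%
  bias compounds over the ~800 site updates of a 200-trial fit into severe
  variance collapse. The moment-matched precision is multiplied by
  (n−d−2)/(n−1).
* **damping** — site updates step a fraction `damping = 0.35` toward the
  moment-matched target. Sequential moment matching from finite samples is
  a noisy fixed-point iteration; with full steps the noise occasionally
  walks the posterior into a prior corner where acceptance collapses and
  the fit cannot recover. Exact (undamped) EP remains appropriate, and is
  used in the toy validations, when there are only a handful of sites.
* **partial updates** — a site whose proposal budget (200 × `min_accepted`)
  runs out with at least `min_accepted_partial = 50` acceptances is updated
  with damping scaled down by its sample fraction instead of being skipped.
  Hard skipping systematically discards exactly the trials that carry the
  lapse signal (lapse responses are the hardest to reproduce) and biases
  the lapse parameters. Sites with fewer acceptances keep their old factor;
  a fit errors out if more than half the sites are skipped in the final
  pass.

The cavity is repaired to a proper distribution before proposing
(precision eigenvalues clipped to [1/100, 1e8], i.e. variances in
[1e-8, 100] on the unit-prior scale), and the global covariance is kept
symmetric positive definite by an eigenvalue floor after every update.
Fits are bit-reproducible given (dataset, settings, seed).

`rejection_abc` implements the brute-force oracle — prior draws accepted
only if every trial in the dataset passes the distance criterion — and is
tractable for a handful of trials; the test suite cross-validates the two
samplers on 1- and 2-trial datasets.

## Model comparison

The posterior predictive likelihood (PPL) of a trial is the fraction of
`n = 15000` simulations (one parameter draw from the EP posterior each)
that reproduce the observed response under the same ε criterion used for
fitting; zero counts are floored at 1/(n+1) before log transforms. Point
predictions take the modal non-timeout choice and the centre of the modal
93.2 ms-wide RT bin among simulations with that choice (ties: earlier bin;
choice ties: left). Match tables cross-tabulate model and participant
correctness over trials where both responded.

Random-effects Bayesian model selection treats the generating model as a
random effect across participants: a variational Dirichlet posterior
(uniform Dirichlet(1) prior) over model frequencies is fitted to the
per-participant log evidences, exceedance probabilities are estimated by
Monte Carlo over that Dirichlet (default 10⁶ draws, seed-controlled), and
protected exceedance probabilities apply the Bayes-omnibus-risk correction
PXP = EP·(1−BOR) + BOR/M, where BOR compares the random-effects free
energy against the null model of equal frequencies. Note that with small
cohorts BOR stays visibly above 0 even for clear-cut evidence, so PXP
saturates below 1 (≈0.98 for 8 participants).

## Synthetic cohorts and what the validations show

`synthetic.make_cohort` emulates the study design: one shared stimulus
set, per-participant random orderings, and responses simulated from a
chosen generating model. Ground truth is either fixed, sampled from the
fitting priors (a well-specified calibration check), or the published
group-mean parameter estimates for this task (`truth_mode="reference"`,
with (mode, SD) NDT pairs inverted to log-normal parameters). Ground truth
is stored beside the data and is never read during fitting.

The validation suites run at sizes chosen to keep a serial single-CPU run
short while leaving the statistical conclusions unambiguous:

* parameter recovery: 10 participant-conditions × 200 trials (truths from
  the priors); ≥85% of the 95% marginal posterior intervals must cover the
  truth (measured ≈90%);
* model recovery: 5 cohorts × 8 participants × 40 trials generated by the
  exact-input model; fitting both input modes and running RFX-BMS must give
  the exact-input model PXP > 0.95 in every cohort;
* sampler cross-validation: EP-ABC vs rejection ABC moments on 2-trial
  datasets at a widened ε = 150 ms (widened only to make rejection
  sampling tractable; both samplers share it).

Synthetic cohorts inherit every idealization of the model: responses
really are generated by the fitted family, lapses really are uniform, and
there is no learning, fatigue, sequential dependency or parameter drift
within a session. Passing recovery tests therefore demonstrates that the
inference machinery is correct and calibrated under the model, not that
the model is adequate for any particular real dataset.

Simulation at the published group-mean parameters (the
`simulate_reference_condition` surface, also what `scripts/acceptance.py`
reports) reproduces the published mean reaction times closely but sits a
few percentage points below the published group accuracies at both
extreme difficulties. The gap is a property of summarizing heterogeneous
per-participant fits by their group mean: a diffusion-limit calculation at
the hardest condition's printed parameters (per-step drift ≈0.04, step SD
≈0.48, bound log-odds ≈0.62) caps accuracy near 57% once mean RT is
matched, so no simulation at those group means can reproduce both
statistics simultaneously.

## Known limitations

* Exactly two alternatives; the log-odds reduction relies on
  mirror-symmetric isotropic generative densities.
* Discrete decision grid: RTs are a lattice (t_d · 93.2 ms) convolved with
  the NDT; data with finer temporal structure are only matched up to ε.
* EP yields a single Gaussian on the unconstrained scale; genuinely
  multimodal posteriors (e.g. lapse-versus-evidence explanations of an
  outlier dataset) are summarized by their moments.
* The evidence estimate inherits Monte-Carlo noise from the acceptance
  rates (SE of a few log units per 200-trial fit); model comparisons
  resting on differences of that order should increase `min_accepted` or
  average over repeated fits.
* `rejection_abc` scales exponentially in the number of trials and is an
  oracle for tiny datasets only.
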