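# Methods

This note documents the models implemented in `schwalearn`, their
assumptions, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Discriminative learning

Learning events pair a cue set with an outcome set, both multiple-hot. Cues
come from a five-word window centred on the target token: the lower-cased
word forms of the *non-centre* window words (the target word form itself is
never a cue, to prevent a trivial direct mapping), plus every diphone of the
boundary-wrapped window string (`#` marks the window edges; windows are
truncated at utterance boundaries and never cross them; a window of total
phone length L yields L+1 diphones, deduplicated within the cue set).

Two input–output structures:

* **functional output** — outcomes are the centre word's inflectional
  function labels, or a single placeholder outcome when the centre carries
  none (keeping cue competition active on every trial). Activation for a
  schwa token sums the weights from its window's word and diphone cues to
  its own function labels (a *sum*, not a mean, across labels).
* **functional input** — the centre's function labels join the cue set
  (omitted in the ablation variant); outcomes are the centre word form plus
  a gesture label for [ɐ] whenever the centre is schwa-final. Activation
  sums the weights from all window cues (words, diphones, functions) to the
  gesture outcome alone.

The delta-rule update uses λ = 1 and η = 0.01 for present and absent
outcomes alike (the standard naive-discriminative-learning parameterization
α = 0.1, β₁ = β₂ = 0.1); both rates and λ are configurable, and results in
the test-suite are exercised only for qualitative properties that are robust
across η ∈ {0.001, 0.01, 0.1}. Absent-outcome updates run over the
*declared* outcome universe (every label in the full event stream,
pre-scanned) by default; a strictly incremental `seen_so_far` universe is
available. Training is a single pass in corpus order — the corpus *is* the
learning schedule — with multi-pass available for equilibrium studies.
Within an event, the prediction V(o) is computed before any update, and
summations run in lexicographic label order so runs are bit-reproducible.

The closed-form equilibrium solves, per outcome, the cue co-occurrence
normal equations C·w = λ·b (pseudo-inverse when C is singular). It is the
expected fixed point of the update when both rates are equal, and serves as
an analytic oracle in the tests; a separately coded brute-force updater
provides an exact (bit-level) second implementation of the update itself.

## Formant preparation

Exclusion rules, in fixed precedence: (1) tokens with vowel duration
< 0.018 s; (2) individual samples with F1 outside [250, 1000] Hz or F2
outside [1000, 2000] Hz; (3) tokens left with fewer than 3 samples (counted
against the range rule when range losses caused the shortfall). The report
counts partition dropped tokens exactly, and filtering is idempotent.

F1 is multiplied by −1 (so that higher tongue position maps to higher
values), then −F1 and F2 are centred and scaled to unit SD within speaker
and dimension (population SD; the negation happens before scoring, which
only flips signs). Per-token time is mapped affinely to [0, 1]; duration
enters models as natural log seconds. The modelling table has one row per
(token, sample, dimension) with the six-level dimension-by-class factor
`dbc`.

## Penalized-spline trajectory engine

A structural analogue of an mgcv-style GAMM ladder, reimplemented with auditable numerics rather than cloned:

* **Bases.** Clamped (open-uniform) cubic B-splines; at the boundary the
  basis degrades to Bernstein polynomials. Penalties are order-2 divided
  differences with respect to the Greville abscissae, so the penalty null
  space is exactly the affine functions of the covariate (for grouped
  factor smooths, order-1 differences whose null space is the per-level
  constants).
* **Terms.** Univariate smooths (k = 10 by default; k = 6 in the ladder),
  full tensor products (row-wise Kronecker of the marginals, one sum-to-zero
  constraint, two penalties), interaction-only partial tensors (sum-to-zero
  centred marginals, explicitly orthogonalized against both marginal
  main-effect blocks), and grouped factor smooths (per-level spline
  deviations with a shared wiggliness penalty and a shared ridge penalty —
  the analogue of a random factor smooth). By-factor smooths replicate the
  block per level; the smoothing parameter is *shared across levels* (one λ
  per penalty direction per term), keeping the search space small; this is
  a deliberate departure from per-level smoothing parameters.
* **AR1.** Residual autocorrelation is handled by pre-whitening within each
  token × dimension series at fixed ρ = 0.8 (first sample weighted by
  √(1−ρ²)); ρ is configurable but never estimated. With ρ = 0 the fit is an
  ordinary penalized regression.
* **Smoothness selection.** Exact Gaussian log marginal likelihood with the
  coefficients integrated out and σ² profiled:
  −2·logML = (n−M)·(log 2πσ̂² + 1) + log|XᵀX+S| − log|S|₊, with M the
  penalty null-space dimension and |S|₊ the pseudo-determinant on the fixed
  range of the total penalty. The search runs derivative-free (Powell) over
  log λ, optionally with random restarts; ladder models warm-start at the
  previous model's optimum. Nelder–Mead is available but converges
  noticeably less well on the ladder's 4–7-dimensional λ spaces.
* **Reporting.** Per-term effective degrees of freedom are traces of the
  term's block of the influence matrix; they are analogues of, and not
  numerically comparable to, mgcv's reference degrees of freedom. Model
  comparison uses ΔML = ML-score(m0) − ML-score(mk), positive when the
  activation model fits better. Residual trimming removes rows beyond 2.5
  standardized residuals once (never iterated) and refits. Percentile
  trajectories are predicted on a 100-point time grid at the 10th–90th
  percentiles of a chosen variable, other covariates at medians/modal
  levels, with grouped factor smooths excluded.

Degenerate inputs: constant covariates, singular penalized systems and
non-finite likelihoods raise informative errors; λ = 0 is allowed only with
fixed smoothing parameters (the marginal likelihood is then improper and
reported as NaN).

## Duration model

Log vowel duration ~ activation + local speaking rate + number of segments,
with crossed random intercepts for speaker and word form, fitted by maximum
likelihood (ML rather than REML so log-likelihoods are comparable across
fixed-effect structures; REML is a flag). The implementation uses a
variance-components parameterization via statsmodels MixedLM; forcing both
variance components to zero reproduces OLS exactly, and the ML optimum is
never below the OLS log-likelihood. Spearman uses midrank ties.

## Synthetic language: what it emulates, and what not

Defaults (the study conditions for all recovery tests): 250 word types, 30%
schwa-final, Zipf exponent 1, 6,000 tokens in geometric utterances of mean
length 8, 6 speakers, 60 function labels in four families (grammatical
class, number, gender, case), bundles of 1–3 labels shared across ~8 schwa
types each (mirroring the order-of-magnitude gap between word types and
function combinations in large spontaneous-speech corpora), and context
predictivity 0.5 (the probability that the pre-target word is a
bundle-identifying signal word). Word classes for schwa types mix content /
complex-function / simple-function words at 48/9/43% — the rounded
proportions of such words in conversational German.

Formant tracks: class-specific quadratic base curves (F1 peaks and F2 dips
mid-vowel; the complex-function class fronted and wide, the simple-function
class retracted and narrow), a duration shift of 40 Hz per unit of centred
log duration (centring at the 55 ms reference keeps base curves inside
plausible ranges; an uncentred shift would only move the intercept), an
uncertainty shift of 30 Hz (F1; −1.5× that on F2) per SD of the latent axis,
fixed per-speaker offsets (20/40 Hz SD), and stationary AR1 noise (marginal
SD 25 Hz, lag-1 coefficient 0.8 — matching the ρ the regression engine
assumes). Samples are one per 8 ms, clipped to [3, 15] per token.

The **latent axis** is the standardized log frequency of the token's
function bundle. It is a generation-side ground truth that the pipeline
must *recover* through network activations — the activations never read it.
Because the axis is a frequency, *both* networks' activations are partially
valid proxies for it (weights grow with exposure); the functional-input
network tracks it more directly through its function cues, which is what
the recovery and contrast tests probe. This also means the input-vs-output
contrast is intrinsically a close contest on synthetic data: the effect
direction is systematic but individual simulated corpora can favour either
measure, which the 10-seed acceptance checks quantify rather than assume.

Not emulated: real acoustics (no audio, no formant tracking error structure
beyond AR1), coarticulation with segmental context (hence
place-of-articulation smooths are optional and off by default), prosody,
dialect and speaker-attitude effects, and any dependence of duration on the
latent axis (durations are log-normal, scaled by speaking rate,
independent of uncertainty — so the duration model's activation effect is
null by construction under defaults). Passing recovery tests therefore
shows that the pipeline's machinery detects and signs the effects it is
pointed at; it does not show that real speech contains them.

## Problem sizes

Default test and acceptance runs use 6,000-token corpora (~1,000–1,500
schwa tokens, ~10,000–20,000 model-table rows), spline bases of 4×4 (tensor),
6 (activation smooths) and 5 (grouped time smooths), and 10 simulation seeds
for stochastic checks — sizes at which a full pipeline run completes in
seconds to a few minutes on one CPU while leaving the ladder's comparisons
well away from their noise floor.
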