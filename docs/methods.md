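# Methods

`serialdep` implements (i) a behavioural analysis suite for serial dependence in
orientation estimation and (ii) a family of ideal observer models in which
history biases arise from efficient sensory encoding and Bayesian decoding in a
temporally stable environment. This note documents the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## The orientation domain

Orientation is axial: θ and θ+180° are the same stimulus. All orientations live
on (0, 180]; signed differences (relative orientations, response errors) live
on (−90, 90], with the tie at exactly ±90° mapped to +90° to mirror the
half-open convention. Circular means and SDs double the angles onto the full
circle, average unit vectors, and map back; in the narrow-dispersion limit the
circular SD equals the linear SD (verified to 1% at σ = 2°). A circular mean
with zero resultant length (e.g. two perpendicular orientations) is an error,
never a silent zero.

## Preprocessing

Per participant (and per delay condition when the design has one), trials whose
response error lies further than three circular SDs from the participant's mean
error are discarded, after which the mean error of the surviving trials is
subtracted from all responses. Both the rejection mean/SD and the final
demeaning are computed in a single pass (no iterative re-estimation), which
makes the operation deterministic; the demeaning uses the arithmetic mean of
the signed errors, which sit far from the ±90° wrap for realistic data.
n-back conditioning pairs each trial with the stimulus n trials earlier *within
the same block*; the first n trials of every block are dropped, so a block of
length L contributes max(0, L − n) rows at lag n.

## Bias quantification

The first derivative of a Gaussian (DoG)

    y(x) = x a w c exp(−(wx)²),  c = √2 e^{1/2}

summarises the bias of response errors y against the relative n-back
orientation x. The constant c makes a equal to the curve's peak height at
x = 1/(w√2); w is constrained to [0.02, 0.07] 1/deg, i.e. peaks between ≈10.1°
and ≈35.4°. Fits pool rows across participants. Because the model is linear in
a given w, the bounded least-squares problem is solved exactly by profiling:
the amplitude has a closed form for each w, and the 1-D profile SSR is scanned
densely on the w bounds and polished with bounded scalar minimisation. This is
the same optimisation problem as generic multi-start curve fitting but
deterministic, and fast enough that the permutation machinery below is exact
rather than approximated.

Group inference uses sign-flip permutations: each draw flips *all* of a
participant's conditioned errors together with probability ½ (preserving
within-participant structure), the DoG is refit on the pooled flipped data, and
the amplitude enters the null distribution. Two-sided p-values double the
one-sided exceedance proportion, count ties as exceedances, cap at 1 and floor
at 2/n_perm. Permutation refits reuse per-participant sufficient statistics
Σ y·g_w(x) on a 51-point w grid (resolution ~10⁻³), which matches the exact
fit far below the Monte-Carlo resolution of the null. Condition contrasts
(same vs. different location; short vs. long delay) shuffle each participant's
two condition labels instead and use the amplitude difference as the statistic.

The model-free per-participant bias is half the difference between mean errors
on clockwise (δ > 0) and counter-clockwise (δ < 0) n-back trials; positive
values mark attraction.

Response variability is summarised by the SD of errors in a 30° sliding window
over δ, demeaned per participant, averaged, and fit with the second derivative
of a Gaussian. We parameterise the 2-DoG as y = a(2w²x² − 1)e^{−(wx)²} + b with
the *reduction-positive* convention: a > 0 means variability is reduced by a
at δ = 0 relative to the offset b. The often-printed form with the opposite
sign of a describes the same curve; we report the reduction with positive sign
because that is the quantity of interest (encoding precision is higher near
recently seen orientations).

## The observer family

A trial proceeds encode → decode:

1. **Prediction.** At each stage the observer predicts the upcoming
   orientation by convolving its knowledge of the previous stimulus with a
   transition model p(θ_t|θ_{t−1}) = p_same·N_wrap(θ_{t−1}, σ_td) +
   (1−p_same)·U(0,180], then mixing the single-step predictions of all past
   trials with exponential recency weights w_lag ∝ exp(−lag/τ), normalised to
   sum to 1. Encoding predictions use past *normalised likelihoods* as
   knowledge; decoding predictions use past *posteriors*. Empty history (first
   trial of a block) gives a uniform prior. The mixture half-life is
   t½ = τ·ln 2 trials, convertible to seconds via the mean trial duration.
2. **Efficient encoding.** Coding resources follow the prediction:
   √J(θ) ∝ p(θ), implemented through the mapping F(θ) = 180 × CDF of the
   encoding prior, which sends the stimulus into a sensory space with uniform
   Fisher information (scaled to (0, 180] so that a uniform prior makes F the
   identity and σ_s reads in degree-equivalent units). The measurement is a
   wrapped-Gaussian sample around F(θ_true) with SD σ_s; the likelihood over θ
   is the sensory Gaussian evaluated at F(θ) — θ enters only through F, so no
   Jacobian appears. Where the prior is high, F is steep and the likelihood
   narrow; the resulting asymmetry (long tail away from the prior peak) is the
   source of repulsive biases.
3. **Bayesian decoding.** The posterior is likelihood × decoding prior,
   renormalised; the report is the posterior's circular mean, optionally plus
   wrapped-Gaussian motor noise.

Variants: `decode_only` replaces the efficient likelihood with a symmetric
Gaussian around θ_true (history enters decoding only; 4 free parameters);
`encode_only` decodes with a uniform prior (history enters encoding only; 4);
`single_prior` uses one shared prediction for both stages (4); `full` keeps
separate transition models and time constants (7). For `single_prior` the
shared prediction is built from past posteriors (the decoding-style buffer);
the defining property — one transition model, one τ, one prediction for both
stages — does not say which knowledge base feeds it, and the posterior-based
prediction is the one that reduces exactly to the plain Bayesian observer when
the likelihood asymmetry vanishes.

Qualitative signatures (reproduced by the test suite on random uniform
sequences): decoding-only observers produce exclusively attractive n-back
biases; encoding-only observers exclusively repulsive ones; the full model
with a slower/broader encoding prediction (τ_enc ≈ 8 trials, σ_td ≈ 11°) and a
faster/narrower decoding prediction (τ_dec ≈ 1.5, σ_td ≈ 8°) yields attraction
at lag 1 turning into repulsion at lags ≈3–8 — the canonical
short-term-attraction / long-term-repulsion pattern.

### Numerics

* Densities live on a uniform grid over (0, 180], 360 bins (0.5°) by default;
  every stored density is renormalised to 1 ± 1e-8. Model fitting uses a
  180-bin grid: doubling the resolution changes estimates by < 0.02° on test
  sequences, well under the 0.05° convergence tolerance.
* Wrapped Gaussians include the k = ±1 wrap terms only when σ > 18°, below
  which the largest neglected term is < 4·10⁻⁶ of the peak.
* Convolutions are circular FFT products; transition kernels are normalised
  numerically on the grid.
* The mixture prior is maintained by the exact geometric recursion
  M_t = P_t + e^{−1/τ} M_{t−1} (renormalised on use), equal to the explicit
  exponentially weighted sum over the full buffer with no truncation. The
  scalar reference implementation keeps the explicit buffer; the two paths
  agree to 1e-10 and are tested against each other.
* F(θ) treats the grid density as piecewise constant (piecewise-linear CDF);
  measurements at arbitrary θ interpolate inside the bin.
* A deterministic single-trial mode (`expected_estimate`) integrates the
  estimate over the measurement distribution with 61-node Gauss–Hermite
  quadrature; it backs the efficient-coding diagnostics (repulsion profile,
  discrimination advantage at the prior peak). Sequence simulation is always
  sampled — a full quadrature over measurement *histories* would branch
  exponentially — with repetitions and common random numbers where averages
  are needed.

## Observer fitting

Models are fit to stacked group-average moving-average bias curves (default
window 30°, matching the variability analysis, on a 3° grid — both are
package defaults, configurable) for lags 1..L. The
objective simulates the candidate on the participants' stimulus sequences with
a fixed seed (common random numbers) and R repetitions and compares curves.

Two objective estimators are provided. The plain SSR (`objective_ssr`)
follows the definition directly but, at small simulation budgets, contains the
Monte-Carlo variance of the model curves, which systematically favours
low-noise candidates. The default grid-stage objective (`cross_ssr`) removes
that term by splitting the repetitions into two independent halves m₁, m₂ and
scoring Σ(m₁−d)(m₂−d): its expectation is the true curve mismatch plus a
candidate-independent constant. Halves additionally use antithetic noise pairs
(±z), a variance-reduction device that leaves the estimator unbiased.

Fitting is two-stage: a coarse grid search (configurable grid; the default
spans σ_s 5–30°, σ_td 5–30°, p_same 0.2–1, τ 0.5–16 trials), with a
screening pass over all nodes followed by a higher-budget re-scoring of the
leaders on fresh noise (avoiding the winner's curse of noisy selection), then
local refinement from the grid optimum. Refinement is either bounded
least-squares on the plain-SSR residuals or Nelder–Mead on the frozen
cross-SSR surface (optionally multi-started from grid leaders in different
σ_s basins, since σ_s trades off against transition-model parameters along a
shallow ridge); the refined point is accepted only if it beats the grid
optimum under a common higher-budget evaluation. Parameter bounds:
0 < σ_s < 60, σ_td > 0, 0 ≤ p_same ≤ 1, τ > 0.

Cross-validation splits each participant's blocks into odd/even halves by
presentation order, fits on the odd half, simulates the fitted observer on the
even-half sequences, and scores the Pearson correlation between predicted and
observed stacked curves. The chance baseline shuffles the model's predicted
responses across trials within each participant (1000 draws by default),
destroying trial correspondence while preserving marginals; p is the fraction
of shuffled correlations at or above the observed one.

## 2AFC inducer pipeline

Each trial of the comparison design carries an inducer (adjustment stimulus)
and a left/right 2AFC pair; the n-back inducer's predicted repulsive influence
assigns the trial to an adapt-right or adapt-left bin (inducer CCW of the
right-hemifield stimulus, or CW of the left-hemifield one, favours "right is
more clockwise"; relative orientation exactly 0° has no prediction and is
excluded with a count). Per participant, bin and location-overlap condition, a
cumulative-Gaussian psychometric Ψ(x) = λ + (1−2λ)Φ((x−α)/β) with λ fixed at
0.01 is fit by Bernoulli maximum likelihood (β is the SD of the Gaussian, in
degrees). The per-inducer bias is 0.5·(PSE_adapt-right − PSE_adapt-left):
repulsion shifts the adapt-right curve toward "right" responses (negative
PSE), so repulsion is negative and attraction positive. The decay of the
group-average bias over lags 1–10 is fit by N(n) = N₀e^{−λn} with half-life
ln 2/λ trials (seconds via the mean trial duration); constant input flags an
infinite half-life, and a sign-alternating profile shows up as near-zero R².

## Synthetic data

The generator emulates the four study geometries (orientation adjustment with
820 trials in 10 blocks; location-varying with 808 in 8; delay-varying with
1212 in 12; 2AFC comparison with 448 in 8) with uniform random orientations on
(0, 180], counterbalanced factor schedules over consecutive trials, observer-
generated responses, optional uniform lapses, and — for the 2AFC template — a
known injected per-lag, per-location bias kernel applied through the choice
probability. Everything is deterministic under (design, truth, seed).

The canonical generating observer (σ_s = 10°, encoding σ_td = 11°, τ = 8
trials, decoding σ_td = 8°, τ = 1.5 trials, p_same = 0.8 at both stages) is
representative of fits to human adjustment data and produces bias amplitudes
of the order ±1–1.5°.

What the synthetic loop does *not* establish: real data contain motor noise
with temporal structure, attention lapses that are not uniform, oblique
effects (orientation-dependent noise), and short-term repulsion between very
dissimilar stimuli (|δ| > 60°) that the observer family does not model.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the pipeline, not the adequacy of the model for any particular
empirical dataset.

## Test problem sizes

The heavier checks run at reduced, fixed sizes chosen as the smallest designs
at which each property is stable: permutation type-I error uses 200 null
datasets of 12 participants × 300 trials at 500 permutations; variant
signatures use 6 participants × 800 trials × 5 repetitions; the full-model
recovery study uses 10 replicates of 6 participants × 300 trials (data curves
averaged over 8 simulation repetitions), a 48-node grid whose encoding and
decoding axes overlap (so the recovered timescale and width orderings are
falsifiable), screening of the top 12 nodes, and two-start Nelder–Mead
refinement. Because σ_s lies on a shallow ridge with the transition
parameters, single replicates at this size occasionally land in a
σ_s-inflated solution of equal objective value; the recovery check therefore
asserts the orderings per replicate and the σ_s tolerance on the median across
replicates. The 2AFC recovery uses 24 participants × 8 blocks with the
injected kernel N₀ = −0.8°, λ = 0.14 (half-life ≈ 4.95 trials).

## Known limitations

* The observer assumes orientation-independent sensory noise (no oblique
  effect) and a posterior-mean readout; alternative readout rules or
  efficient-coding objectives (redundancy, reconstruction error) are not
  implemented.
* Observer models are fit to adjustment (estimation) data only; the 2AFC
  pipeline is analysis-only.
* The repulsion observed between highly dissimilar successive stimuli in some
  datasets is outside the model family's scope.
* Permutation p-values are floored at 2/n_perm; exact zero p-values are never
  reported.
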