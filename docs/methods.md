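# Methods

## Task model

A session crosses *environment* (stable vs. reversal of the cue-target
contingency) with *prior instruction* (stability vs. reversal announcement),
one 80-trial block per cell, block order pseudo-randomized per participant.
The contingency is 0.7; reversal blocks flip the cue-target mapping between
trials 40 and 41. Trials divide into three phases at the 1-based boundaries
27 and 53 (initial learning, change expectation, adaptation), inclusive on
the left phase (trial 27 belongs to phase 1, trial 54 to phase 3).

Expectedness is **constant-coded** against the first block half: `u = 1` when
the target falls at the location the initial contingency favors, for the
whole block. After a reversal the trials that obey the new rule therefore
carry `u = 0`. `valid_now` tracks validity under the rule currently in force
(`valid_now = u` before the reversal, `1 − u` after).

Sequence generation places exact per-phase numbers of `u = 0` trials — the
canonical quadruples are stable/true 9, 6, 9; stable/false 8, 8, 8; and
reversal (either prior) 8, 13, 19 — by shuffling within phase segments and
rejection-sampling until no three consecutive trials violate the contingency
currently in force. The run constraint is deliberately stated on `valid_now`,
not on `u`: a constraint on constant-coded `u` is infeasible in reversal
blocks (19 zeros among the 27 adaptation-phase trials cannot avoid a
three-run when only 8 ones are available to separate them), whereas
currently-unexpected trials occur at a rate near 0.3 in every phase and the
constraint is satisfiable everywhere. For the phase that straddles the
reversal, its unexpected-count budget is split across the boundary so each
half's realized validity is as close as possible to the nominal contingency
(canonically 4 of 13 before the flip, 9 after). Both tones occur equally
often and the target side is balanced through the rule symmetry
P(r|ht) = 1 − P(l|ht) = P(l|lt). All randomness is driven by
`numpy.random.default_rng(seed)`; a fixed seed reproduces sequences bitwise.
Blocks of non-canonical length scale the phase boundaries proportionally and
derive per-phase counts from the contingency.

## Learning and response models

Beliefs follow the Rescorla-Wagner rule `v_t = v_{t−1} + α (u_t − v_{t−1})`
with `v̂_t = v_{t−1}` the pre-observation prediction. The initial belief is
v0 = 0.5 (an uninformative start each block; configurable). The recursion is
evaluated as a first-order IIR filter (`scipy.signal.lfilter`), which is
exact and fast. A single trajectory for the coded outcome suffices because
the rule symmetry makes per-cue twin trajectories mirror images.

Predictive-task choices use the binary softmax
`P(i=1) = expit(β (2 v̂ − 1))` (log-domain safe at extreme β; β = 0 is the
chance limit). Reactive-task response speeds are Gaussian around the affine
mean `u (ζ₁ + ζ₂ v̂) + (1 − u)(ζ₁ + ζ₂ (1 − v̂))` with residual SD σ — the
affine model needs a noise distribution to define a likelihood, and Gaussian
residuals on speed-transformed RTs are the standard choice. The simulator
truncates speeds at zero. Simulated reactive accuracy is Bernoulli with
`p = clip(0.90 + 0.07 · belief-in-presented-location, 0, 1)`: no accuracy
model is fitted, but the model-free accuracy pipeline needs accuracy data
with an expectedness gradient and a mean near 95%. Omissions are
representable (`response_made` mask, excluded from all likelihoods) and
emitted at a configurable rate, 0 by default. The response-speed likelihood
uses all responded trials, not correct trials only.

## Estimation

Parameters are estimated per participant × block in an unconstrained space
(logit α; log β; log σ²; ζ identity) with independent Gaussian priors:
logit α ~ N(logit 0.2, 4), log β ~ N(0, 4), ζ₁ ~ N(2, 4), ζ₂ ~ N(0, 4),
log σ² ~ N(log 0.01, 4). These are weakly informative and centered on
plausible values (RT ≈ 0.5 s ⇒ RS ≈ 2); all are configurable. MAP
optimization is multistart BFGS (8 starts: prior mean plus seeded jitter of
half a prior SD; objective tolerance 1e-6), curvature by central finite
differences (step 1e-4), and the log model evidence is the Laplace
approximation `log p(y, θ̂) + d/2 · log 2π − ½ log det(−H)`. Fits require at
least 10 usable trials; non-positive-definite curvature flags the fit
unconverged rather than raising. Note that constant, rule-consistent choices
are *not* uninformative about α (rising beliefs raise the likelihood of
repeated matching choices); the flat-likelihood regime arises when β → 0,
e.g. for incompressible alternating choices, and there the α estimate falls
back to its prior mean.

## Model selection

Per-subject evidence for a model is the sum of its four block LMEs (blocks
are fit independently). Random-effects BMS runs the variational
Dirichlet-multinomial scheme (assignments ∝ exp(lme + ψ(α_k) − ψ(Σα));
α_k = α0 + Σ assignments; α0 = 1) to convergence of the concentrations
(tolerance 1e-8). Exceedance probabilities are exact via the Beta CDF for two
models and seeded Monte Carlo (10⁶ Dirichlet draws) otherwise. The Bayes
omnibus risk compares the fitted model's variational free energy against the
equal-frequency null, `BOR = 1/(1 + exp(F1 − F0))`, and
`pxp = ep · (1 − BOR) + BOR/K`. The comparison model shipped in-package is a
static-belief observer (α pinned at 0, belief fixed at v0); the BMS machinery
accepts any external LME matrix, so richer comparators (e.g. hierarchical
volatility-tracking filters, which this package deliberately does not
implement) can be plugged in.

## Model-free measures

RT outliers are masked in a single pass per participant and task: trials more
than 2 SDs from that participant's mean RT over responded trials (not per
condition — the statistics are participant-level). Participant inclusion
uses the same 2-SD rule on group accuracy with the boundary counting as
within. Cueing effects are unexpected-minus-expected means per
participant × condition × phase — RTs from correct, responded, non-outlier
trials; accuracy in percentage points from responded trials. Choice
probability is the mean of constant-coded choices. A switch is a choice
differing from each of the four preceding choices (flags only from trial 5;
windows containing an omission never flag; the rate divides by T − 4
eligible trials). Under this strict binary reading two consecutive switch
flags are impossible, so the removal of consecutive flags — implemented for
contract fidelity — never fires. Sliding-window choice series use window 4,
step 1, reported at 1-based window start positions.

## Group statistics

The within-subject factorial ANOVA (up to four fully-crossed factors, one
observation per subject and cell, replicates cell-averaged first) is
computed via orthonormal effect contrasts: for effect E with Kronecker
contrast C, subject scores Z = MC give SS_eff = n·‖mean Z‖², SS_err =
(n−1)·tr(cov Z), F = (SS_eff/df1)/(SS_err/df2), partial η² =
SS_eff/(SS_eff+SS_err) — algebraically the classical decomposition with each
effect tested against its subject interaction. Mauchly's test and the
Greenhouse-Geisser ε come from the covariance of the contrast scores; GG is
applied when Mauchly's p < .05 (force-on/off switches provided; 2-level
effects are uncorrectable, ε = 1). This is hand-implemented because no
installed library covers more than two within factors; it is cross-checked
against pingouin on 1-2 factor designs and against brute-force
sums-of-squares in the tests.

The cluster-based permutation test thresholds position-wise paired t values
at the two-tailed critical t (p < .05, df = n−1), forms signed contiguous
suprathreshold clusters scored by summed t, and builds the null from
per-subject sign flips of the condition differences (equivalent to
within-subject condition swaps). The identity flip is always included, so
cluster p ≥ 1/n_perm; an exhaustive 2ⁿ enumeration mode exists for small n.
Power analysis for the paired t-test uses the noncentral t distribution
(noncentrality dz·√n, df n−1, two-tailed) and returns the minimal n meeting
the target power.

## Synthetic population

Defaults emulate the study conditions: 32 participants, both task versions
sharing identical trial sequences, four blocks of 80 trials at contingency
0.7. Generative parameters are sampled on transformed scales — predictive
logit-α cell means 0.35/0.35 (stable) and 0.5 true vs. 0.3 false (reversal),
SD 0.7; log-β means 6 true vs. 3 false (stable) and 4.5 (reversal), SD 0.5;
reactive α 0.6 everywhere; ζ₁ = 2.0, ζ₂ = 0.5, σ = 0.2 (RT ≈ 500 ms) — so
that the qualitative effect directions of interest (slower updating under a
false stability prior; noisier, switchier choices under a false volatility
prior) are present by construction. The generator reproduces the *structure*
the analysis assumes, not human data: no sequential RT dependencies, no
lapses or fatigue, no per-cue asymmetries, and parameters that are exactly
RW-generated. Passing tests therefore certify the correctness and
recoverability of the machinery, not empirical claims about behavior.

## Validation

Parameter recovery samples one population, simulates 20 replicate
predictive-task studies with distinct seeds, refits every block, computes
per-condition Pearson correlations between generating and recovered α and β
across the 32 participants, averages r over replicates, and converts to
Cohen's f² = r²/(1−r²) with f² ≥ 0.35 as the pass criterion (equivalently
mean r ≥ √(0.35/1.35) ≈ 0.509). Posterior-predictive checks bin trials by
the fitted model's v̂ into four equal-width bins on [0, 1] (quantile binning
would be a reasonable alternative; equal-width is fixed here) and compare
observed with model-simulated per-bin means, averaged within and then across
subjects. `simulate_and_reanalyze` closes the loop by regenerating one
dataset from fitted parameters and rerunning the model-free battery.

Problem sizes throughout (20 × 32 × 4 fits in recovery; 500 null simulations
at 200 permutations for the cluster-test calibration; 10⁶ draws for
Monte-Carlo exceedance) were chosen so the full suite completes in minutes
on a single CPU while keeping Monte-Carlo error well inside the assertion
tolerances.

## Known limitations

* The group-level statistics of the original human dataset are not
  reproducible here (the dataset is unreleased); all quantitative checks run
  on synthetic data and directional effects only.
* The original estimation toolbox's prior tables are not public; the priors
  above are this package's own defaults, so recovered magnitudes need not
  match published ones even when orderings do.
* Only the RW and static-belief observers are implemented; hierarchical
  volatility-tracking models must be supplied externally as LME matrices.
* The ANOVA handles balanced, fully-crossed within-subject designs only (no
  between factors, no missing cells, GG but not Huynh-Feldt correction).
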