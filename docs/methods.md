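# Methods

## The game and the decision rule

The task is a repeated two-option hide-and-seek game. On each of 60 trials a
*hider* picks one of two locations and a *seeker* simultaneously guesses one;
the seeker earns the trial's point iff the guesses match, the hider iff they
differ (zero-sum complementary payoffs). With `p_op` the probability that the
opponent plays option 1, the expected payoff difference between one's own
options is

    dV = 2 p_op - 1   (seeker),      dV = 1 - 2 p_op   (hider),

and every value-based agent shares one stochastic policy,

    P(a = 1) = 1 / (1 + exp(-(dV + b) / beta)),

with behavioural temperature `beta > 0` and option bias `b`. The agents
differ only in how they form `p_op` (or, for the value learners, the action
values directly):

* **RB** — a non-reactive schedule with exactly round(0.65 x 60) = 39 trials
  on a preferred option, in seeded shuffled order.
* **BN** (biased Nash) — `dV` pinned at 0; only the bias acts. This is the
  mixed-strategy equilibrium policy and is unexploitable by construction.
* **WSLS** — win-stay/lose-switch. Rewards in {0, 1} are re-centred to a
  signed reward (+1 win, -1 loss) and the chosen/unchosen values are set to
  +-R, so the rule expresses a strict stay/switch preference whose
  determinism is governed by `beta`.
* **RL** — Rescorla-Wagner updating of the chosen action's value with
  learning rate `alpha`; equivalent to WSLS on the chosen arm when
  `alpha = 1`.
* **Inf** (influence learning) — tracks the opponent's choice probability
  with a prediction-error step `eta (a_op - p)` plus an influence correction
  `w p (1-p) (1 - 2 a_self - beta logit(p))` accounting for how one's own
  action steers the opponent. The estimate is clipped to
  [1e-4, 1 - 1e-4] (clip events are counted).
* **0-ToM** — a Gaussian belief `(mu, Sigma)` over the opponent's choice
  log-odds, assumed to drift with volatility `sigma`: variance update
  `Sigma_t = 1/(1/(Sigma + sigma) + s(mu)(1 - s(mu)))`, then mean update
  `mu_t = mu + Sigma_t (a_op - s(mu))`. As `sigma -> 0` this converges to
  fictitious play (tracking the empirical choice frequency).
* **k-ToM** (k = 1, 2, 3) — recursive mentalizers described next.

## The k-ToM learner

A k-ToM learner assumes its opponent is itself a kappa-ToM learner with
kappa < k, with unknown parameters x^kappa = (log sigma_op, log beta_op).
It maintains, per candidate level kappa:

* a posterior probability lambda^kappa that the opponent reasons at level
  kappa (for k = 1 the degenerate point mass lambda = 1);
* a Gaussian belief (mu^kappa, Sigma^kappa) over x^kappa, drifting with the
  learner's own volatility parameter sigma (variance inflation `+ sigma I`
  per trial).

Level kappa predicts the opponent's next action with probability
`s(v^kappa(x))`, where `v^kappa` is the softmax log-odds a kappa-ToM learner
(in the opponent's role, with parameters x, zero bias) would emit after the
observed history. Per trial the learner:

1. evaluates each level's `v^kappa` at the posterior mean and its gradient
   `W` w.r.t. x (central finite differences, step 1e-3);
2. corrects each level prediction for parameter uncertainty,
   `p^kappa = s(v / sqrt(1 + a W'(Sigma + sigma I) W))` with `a = 3/pi^2`
   (the same probit-style moment closure used for the Gaussian expectation
   of a sigmoid everywhere in the package; a 31-node Gauss-Hermite
   quadrature serves as its oracle in the tests);
3. reweighs lambda by each level's likelihood of the observed opponent
   action and renormalises;
4. updates each level's Gaussian: precision
   `Sigma_t^-1 = (Sigma + sigma I)^-1 + s'(v) lambda W W'`, then
   `mu_t = mu + lambda Sigma_t W (a_op - s(v))`. If an update breaks
   positive definiteness the covariance is symmetrised and its eigenvalues
   floored at 1e-8 (repairs are counted; they are rare);
5. acts on the lambda-weighted mixture of the corrected level predictions.

**Online evaluation of `v^kappa`.** Literally replaying a kappa-ToM learner
over the full history at the current posterior mean (and at four perturbed
parameter values for the gradient) costs O(T^2)-O(T^4) per likelihood
evaluation for k = 2, 3, which is infeasible for the ~6k-fit cohort stage.
Instead each level carries a bank of five *incrementally updated* simulated
opponents anchored at `mu + {0, +-h e1, +-h e2}`; the bank is advanced one
trial at a time at the current parameter estimates, so each trial is O(1) in
history length. The replay definition is kept as a reference implementation
(`ktom.agents.ktom_simulate_level`) and the tests verify that the online
values converge to the replayed ones as the parameter posterior settles
(difference ~1e-3 at 60 trials with a near-static posterior).

The engine is implemented twice: a recursive, readable pure-Python version
(`ktom._ktom_reference`) and a flattened numba version (`ktom._ktom_core`)
used by simulation and fitting; a test asserts their trajectories agree to
~1e-8. For k = 3 one 60-trial likelihood evaluation costs ~2 ms.

## Approximation accuracy of the belief recursion

The 0-ToM update is a small-variance Laplace-style approximation. Against a
dense-grid exact Bayes filter (step 0.01 on [-10, 10], identical diffusion),
its one-step posterior mean is accurate to < 0.04 for volatilities up to
0.5; over full 60-trial sequences, however, trajectory lag accumulates to a
worst-case mean discrepancy of ~0.13-0.22 even at small volatility (the
recursion systematically under-responds relative to the exact skewed
posterior, and the two trajectories then process identical data from
different states). This is a property of the update rule itself, not of the
implementation; the tests document both the one-step accuracy and the
sequence-level divergence, and the fictitious-play limit (volatility -> 0,
mean -> empirical log-odds) is verified separately.

## Default agent parameters

All synthetic agents share one calibration, frozen once:
`beta = 0.25`, `sigma = 1.0` (ToM volatility), `eta = 0.3`, `w = 0.5`
(influence), `alpha = 0.7` (RL), `bias = 0`. The calibration was chosen so
that (a) the documented competitive dynamics appear at 60 trials with
human-scale magnitudes — mentalizers exploit the frequency tracker
(1-ToM vs 0-ToM mean net rate ~ +0.08), influence learning beats 0-ToM
(~ +0.09) but loses against 1-ToM (~ -0.10), biased Nash stays within
+-0.013 of zero against every opponent — and (b) the strategies are as
behaviourally distinguishable as this model family allows at 60 trials.
At high temperatures (beta ~ 1.5) all of these regularities disappear:
every agent plays within a few percent of chance and model comparison
collapses onto the cheapest model.

## Model fitting and evidence

Each of the 8 models is fitted to each 60-trial session independently by
MAP + Laplace. Free parameters (BN: bias; WSLS: beta, bias; RL: alpha,
beta, bias; 0-ToM and k-ToM: sigma, beta, bias; Inf: eta, w, beta, bias)
live in an unconstrained space (log for sigma/beta, logit for
alpha/eta/w, identity for bias) with independent standard-normal priors —
weakly informative and symmetric. Fitting replays the observed session:
states are updated with both observed actions, never with a simulated
opponent. The MAP is found by multi-start L-BFGS-B (restart points drawn
from the prior with a fixed per-fit seed; the first of equal-best optima by
restart index is kept; box bound +-8), and

    log p(a | m) ~= log p(a | theta*) + log prior(theta*)
                    + (d/2) log 2 pi - (1/2) log det H,

with H the finite-difference Hessian of the negative log joint at the MAP.
If H is not positive definite the evidence falls back to a BIC-style
penalty and the fit is flagged. Laplace evidences agree with dense-grid
marginalisation to well under 1 nat for the 1-2 parameter models. Session
posteriors are softmax of the log evidences (uniform model prior),
max-subtracted for stability.

Default optimisation settings are 8 restarts / 200 iterations; cohort-scale
runs (the end-to-end tests and the acceptance script) use 2 restarts with a
capped iteration budget (60 and 45 respectively), which changes individual
evidences by far less than the between-model gaps that drive the analyses.

## Phenotypes

For one participant (16 sessions: 4 opponents x 2 framings x 2 repetitions):

* **Flexibility** between two conditions is
  `f = 1 - sum_m p(m|a1) p(m|a2)`, the posterior probability that different
  strategies were used. `f_framing` averages over the 8 matched
  (opponent, repetition) pairs; `f_repetitions` over the 8 matched
  (opponent, framing) pairs — matched pairs hold everything but the
  contrasted factor constant. The flexibility gap is
  `delta_f = f_framing - f_repetitions`.
* **ToM sophistication** is `k = sum_k k p(m = k-ToM | a)` over the full
  eight-model posterior (not renormalised over the ToM subset; a
  renormalised variant is available behind a flag). `k_social` and
  `k_nonsocial` average over each framing's 8 sessions;
  `delta_k = k_social - k_nonsocial`.

The RB opponent is included in all averages by default (`include_rb=False`
excludes it). Because posteriors are never point masses at 60 trials, both
flexibility scores share a positive floor (~0.6 under the default
calibration); the floor cancels in `delta_f` and in group contrasts, which
is what the analyses read out.

## The synthetic cohort

48 participants (24 AS-like, 24 NT-like), 16 sessions each. Per opponent
condition a strategy is drawn from the participant's social-framing
repertoire; the matched non-social session keeps it with probability
`1 - switch_rate_framing` (else re-draws from the non-social repertoire),
and each second repetition re-draws with probability
`switch_rate_repetition`. Group profiles:

* **NT-like**: non-social repertoire weighted toward WSLS/RL/0-ToM,
  social repertoire toward 1-ToM/2-ToM; `switch_rate_framing = 1`
  (framing-specific strategy choice), `switch_rate_repetition = 0.30`.
* **AS-like**: both repertoires dominated by influence learning
  (base weight 0.75) and low switch rates (`0.08` across repetitions,
  `0` across framings at baseline). Each AS participant additionally draws
  an "NT-likeness" latent `u ~ Beta(0.8, 2.5)` that linearly tilts the
  social repertoire toward the NT social profile and raises both switch
  rates (`switch_framing = u`, `switch_repetition = 0.08 + 0.55 u`).
  `u = 0` reproduces the pure influence-learner participant; the graded
  latent provides the inter-individual variation in true phenotypes without
  which phenotype-symptom regression would have no estimand.

Per-participant repertoires are Dirichlet draws (concentration 8) around
the group/base mix, modelling idiosyncratic preferences. Opponents in the
sessions are the four experimental agents (RB with a random preferred
option per session; 0/1/2-ToM at the default calibration, bias 0); 3-ToM
exists only in the fitted model space, never as an opponent.

Symptom scores are generated from the *true* phenotype contrasts implied by
each participant's generative settings:
`social = round(10 - 3 delta_k_true - 5 delta_f_true + N(0, 1.5))`,
truncated at zero; the stereotyped-behaviour score is independent noise
(`round(8 + N(0, 2.5))`, truncated at zero), so it carries no phenotype
signal by construction.

What the generator deliberately does *not* emulate: reaction times and
missed responses, payoff-magnitude effects, debriefing/credibility
variables, and any within-session strategy mixing (each session is played
by exactly one strategy). Passing end-to-end tests therefore demonstrate
that the pipeline recovers the structure this generator encodes — not that
real participants behave like these agents.

## Cohort statistics

Classification uses a plain L2-regularised logistic regression (C = 1,
z-scoring fitted inside each training fold) on the 8 performance features
(net correct rate per opponent x framing, averaged over repetitions),
optionally augmented with the 4 phenotypes, evaluated by leave-one-out
cross-validation; chance is assessed by re-running the whole LOO loop under
1000 seeded label permutations, `p = (1 + #{perm >= obs}) / (1 + 1000)`.
Symptom regression is OLS of the social subscore on the four phenotypes
(overall R^2, F) with univariate one-sided follow-ups on `delta_k` and
`delta_f` (direction of interest: negative).

## Problem sizes and reproducibility

The end-to-end analyses run on the full 24+24 cohort (768 sessions, 6144
model fits) at the reduced optimisation settings; tournaments use 200
games x 60 trials per pairing; model recovery uses 30 sessions per
generating strategy, parameter recovery 50 simulated subjects per
parameter. Every stochastic stage derives its stream from one base seed via
`numpy.random.SeedSequence`, and rerunning any stage with the same seed is
bit-reproducible.

## Known limitations

* The 2-ToM vs 1-ToM tournament margin is ~0 at 60 trials under every
  calibration we examined: a 1-ToM facing an opponent its model cannot
  predict rationally inflates its estimate of the opponent's temperature
  (log beta-hat reaches ~+2 within 60 trials) and converges to near-uniform,
  near-unexploitable play. 2-ToM's mentalizing shows clearly against 0-ToM
  (+0.09) but yields no measurable edge over 1-ToM.
* Recursion depths are only weakly identifiable from a single 60-trial
  session: 1/2/3-ToM generate mutually similar behaviour (and look like BN
  against the non-reactive RB opponent), so depth recovery by model
  comparison is substantially below the recovery of the non-recursive
  strategies. Group-level sophistication contrasts survive because they
  average over sessions and subjects.
* The belief recursion tracks exact Bayesian filtering only loosely over
  long sequences (see above); all downstream quantities inherit this
  approximation.
* Influence learning at high `eta` and low temperature is behaviourally
  equivalent to WSLS for a seeker (following the opponent's last action is
  exactly win-stay/lose-switch); the default calibration avoids that corner
  but near-equivalences of this kind bound what model comparison can
  resolve at 60 trials.
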