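# ktom

Computational phenotyping of behavioural repertoires in repeated dyadic
competitive games.

## The problem

In a repeated two-option hide-and-seek game, success depends on predicting —
and steering — an adaptive opponent. People differ in *which* adaptation
strategy they bring to such games and in *when* they switch strategies:
knowing that the opponent is an intentional agent (a social framing) can
recruit recursive theory-of-mind ("I believe that you believe..."), whereas
the same choice data under a gambling framing tends to be produced by
simpler heuristics. Two summary quantities capture this: the repertoire's
**ToM sophistication** k̂ (the posterior-expected recursion depth of the
strategy that best explains a choice sequence) and its **flexibility** f̂
(the posterior probability that different strategies were used in two
conditions). These phenotypes separate clinical groups and track social
symptom severity, which makes them candidates for objective behavioural
markers. This package is for computational psychiatrists and cognitive
modellers who want that entire analysis chain as tested, reproducible code.

## What the package does

- **Game engine** — the competitive payoff table, the shared softmax policy
  `P(a=1) = s((ΔV + b)/β)` with `ΔV = ±(2p_op − 1)`, session containers, and
  the net-correct-rate performance metric `(n_c − n_i)/(n_c + n_i)`.
- **Agents** — the eight-strategy repertoire: biased-random schedule (RB),
  biased Nash (BN), win-stay/lose-switch (WSLS), reinforcement learning
  (RL), influence learning (Inf), and meta-Bayesian k-ToM learners for
  k = 0..3, including the recursive level-posterior machinery (numba
  engine + pure-Python reference implementation).
- **Synthetic cohort** — a generator for ground-truth cohorts (24 AS-like +
  24 NT-like participants × 16 sessions: 4 opponents × 2 framings × 2
  repetitions) with symptom scores linearly coupled to the true phenotype
  contrasts.
- **Inference** — per-session MAP + Laplace log evidence for all 8 models
  (standard-normal priors in transformed parameter space), evidence
  matrices, and stable model posteriors.
- **Phenotypes** — f̂ (framing and repetition variants), k̂ (social and
  non-social), and their contrasts Δf̂, Δk̂.
- **Cohort statistics** — leave-one-out logistic classification of group
  from performance (optionally + phenotype) features with a permutation
  null, and phenotype→symptom OLS regression.

## Worked example

```bash
ktom simulate --seed 3 --n-per-group 2 --out demo
ktom fit      --sessions demo/sessions.csv --seed 3 --out demo
ktom phenotype --evidence demo/evidence.tsv --cohort demo/cohort.csv --out demo
ktom report   --results demo
```

The report for this 4-subject demo prints:

```
# Run summary

Sessions: 4 subjects, 64 games, 3840 trials.

Mean net correct rate by opponent x framing:
framing   non-social  social
opponent
0-ToM          0.004   0.129
1-ToM         -0.162  -0.083
2-ToM         -0.100  -0.083
RB             0.054   0.017

Group-mean phenotypes:
       f_framing  f_repetitions  k_social  k_nonsocial  delta_f  delta_k
group
AS         0.605          0.636     0.006        0.030    -0.03   -0.024
NT         0.907          0.607     0.861        0.003     0.30    0.858
```

Reading it: net correct rates near zero mean chance-level performance
against the unexploitable agents, positive values mean the seeker is beating
that opponent. In the group phenotype table the AS-like participants sit
lower than NT-like on social sophistication `k_social` and on both
flexibility scores, and only the NT-like group shows a positive flexibility
gap `delta_f` — strategy switching driven by the framing over and above the
base switching rate. (At this demo size the numbers are noisy; the test
suite runs the full 24+24 cohort.)

The same pipeline is available as library calls
(`ktom.cohort.generate_cohort`, `ktom.inference.fit_cohort`,
`ktom.phenotypes.cohort_profiles`, `ktom.stats.loo_classify`, ...); the CLI
is a thin wrapper.

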