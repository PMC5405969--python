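# Methods

## Task design

A session is 120 two-armed bandit games (notionally four blocks of 30; blocks
are an organizational label and carry no balancing constraint). Each game
fixes a generative mean for the left and right option: one option is
anchored at 40 or 60 points and the other offset by 0, 5 or 10 points up or
down. Single-trial payoffs are Gaussian with SD 8 points around the chosen
option's mean, rounded to integers and clipped into [1, 100] — the range is
part of the task, the round-and-clip mechanism is this package's choice of
the simplest rule consistent with an integer point display. The first four
trials are forced: either two plays of each option (equal information,
`[2 2]`) or three-and-one (unequal, `[1 3]`). The free choices that follow
number 1, 6 or 11 (the horizon), 40 games each.

Counterbalancing: the stated design balances horizons exactly and leaves the
nesting of the remaining factors open. We balance hierarchically — within
each horizon the two information conditions split the games exactly in half;
within each (horizon × information) stratum of 20 games the 12 design cells
(anchor side × offset magnitude × offset sign) each receive their floor
share and the remainder is assigned by sampling cells without replacement;
the 40/60 anchor value and, in unequal games, the more-informative side are
each balanced 10/10 within the stratum. Every marginal balance the task
description states is therefore exact, and the residual freedom is
randomized. The order of the four forced trials is a uniform random
permutation of the required multiset; game order is a random interleaving.
All randomness in a session flows from a single generator seeded from the
configuration.

## Generative agents

Simulated subjects choose on the first free trial by a Bernoulli draw from
the logistic choice probability

    p = 1 / (1 + exp(−(ΔR + A·ΔI + B·Δl) / σ)),

the closed-form consequence of adding logistic noise to option values and
choosing the maximum; we implement the direct Bernoulli draw and treat the
two formulations as one contract. ΔR is the difference of unweighted means
of the forced-trial rewards (reference option minus the other; 1-vs-3
samples in unequal games are not reweighted), ΔI is +1 when the reference
option is the more informative one and 0 in equal-information games, Δl is
+1 when the reference option is on the left. The reference option is the
more informative option in unequal games and the left option in equal games;
the model's label symmetry (negating ΔR, ΔI, Δl and complementing the
choice leaves the likelihood unchanged, a tested invariant) makes this
convention immaterial.

Only the first free choice carries the experimental signal. Later free
choices are filled in with the same rule applied to running observed means
(with ΔI the sign of the sampling-count difference, and A active only in
unequal-information games, where the condition defines it), purely so that
sessions are structurally complete and task performance is computable; no
analysis here estimates parameters from post-first choices. Reaction times
are lognormal plumbing (default median 1065 ms, log-SD 0.35, giving means
near those reported for this paradigm) and never influence choices.

Population defaults. Subject parameters are drawn per treatment arm from
Gaussian (A, B) and Gamma (σ) population distributions. The default decision
noise means and SDs per (treatment × horizon × information) cell are the
published group-level estimates for this task (placebo equal-information
4.162/6.369/9.562 points at horizons 1/6/11, and so on), converted to Gamma
shape/scale by moment matching. The information bonus is not tabled in that
report, so we set means of 1, 5 and 6 points at horizons 1, 6 and 11 (SD 2)
— positive, rising with horizon, identical across treatments, matching the
directions shown graphically — and a small spatial bias (mean 0.5, SD 1.5
points). These defaults are fixed study conditions, not tuning knobs.

## Hierarchical model and priors

Per condition cell n and subject s:

    A_ns ~ Gaussian(μ_A^n, σ_A^n)      (cells: treatment × horizon)
    B_ns ~ Gaussian(μ_B^n, σ_B^n)      (cells: treatment × horizon × info)
    σ_ns ~ Gamma(shape k^n, scale λ^n) (cells: treatment × horizon × info)

A is indexed by treatment × horizon only and is informed solely by
unequal-information choices, since ΔI = 0 elsewhere makes it unidentifiable.
Hyperpriors are broad: population means Gaussian(0, 1000) (SD 1000); the
precision 1/σ² of each population Gaussian Gamma(0.001, 0.001) shape–rate;
k and λ Exponential with rate 0.001 (mean 1000).

The precision reading of the Gamma(0.001, 0.001) hyperprior deserves a note,
because the alternative — placing it on the SD itself — is quantitatively
absurd in a way that is easy to miss: that density is nearly log-uniform
over e^(±1000), so roughly 70% of its mass lies below 10^-150, and the joint
posterior then concentrates at a degenerate point where the population SD
underflows and the subject level collapses onto its mean. Putting the vague
Gamma on the precision — the universal convention of BUGS-family samplers,
whose Gaussians are parameterized by precision — keeps the posterior proper
in practice (the rate term bars the SD→0 limit) and makes the update
conjugate. We verified the collapse empirically before settling on the
precision reading.

## Sampler

Sampling is adaptive Metropolis-within-Gibbs, chosen because the model's
conditional structure vectorizes cleanly over (cell × subject) arrays:

- subject-level A, B: elementwise Gaussian random-walk proposals, accepted
  per (cell, subject);
- subject-level σ: the same on log σ (Jacobian included);
- population means: exact conjugate Gibbs draws;
- population precisions: exact conjugate Gibbs draws;
- k, λ: log-scale random walks.

Plain one-coordinate walks mix poorly across two well-known geometric
features: the funnel (small population SD pins subject values to the mean)
and the Gamma shape–scale ridge (k and λ are strongly anti-correlated when
only 22 subjects inform them). Each sweep therefore also makes joint moves:
translating a whole Gaussian family (mean plus all subject values),
rescaling a family about its mean together with its SD, rescaling λ together
with every σ in its cell, and sliding (k, λ) along the ridge (k·c, λ/c;
repeated 20× per sweep — it needs no likelihood evaluation). With these
moves, split R-hat at the default schedule on a full-scale synthetic study
is ≤ 1.07 for every parameter; without them the hyperparameters sit near
2.3. All acceptance ratios include the appropriate Jacobians; proposal
scales adapt toward 44% acceptance during burn-in only, so retained draws
come from a fixed kernel.

Schedule and bookkeeping: four independent chains, 500 burn-in sweeps
discarded, 5000 post-burn-in sweeps per chain with every 5th retained — 1000
draws per chain, 4000 total. Chains are seeded by spawning a seed sequence
from the user's single seed; equal seeds reproduce draws exactly. R-hat is
computed with arviz and non-convergence is surfaced as a warning, never
silently. Initial states are drawn within a numerically safe range
(population means Gaussian(0, 3), SDs uniform on [0.5, 3], k uniform on
[1, 8], λ on [0.5, 2], subject values from those populations with σ clipped
to [0.5, 50]) — overdispersed relative to the posterior while avoiding the
astronomically remote starts literal hyperprior draws would produce.

Summaries follow the reporting convention of hierarchical fits of this task:
subject-level posterior means (with central 95% intervals) for individual
differences, population-level posterior medians for inference, and the
implied Gamma mean k·λ and SD √k·λ of decision noise for group-level tables.

## Statistics

The model-free statistic is the per-(subject × treatment × horizon × info)
proportion of games whose first free choice took the option with the lower
mean observed forced-trial reward — "lower expected value" is read as what
the subject could know, not the generative mean. Games with tied observed
means are excluded; a cell with no eligible games is flagged missing rather
than zero.

The factorial ANOVA on parameter estimates is a standard fixed-effects
between-cells analysis (statsmodels OLS + anova table), validated against a
brute-force sums-of-squares oracle to 1e-10 and the F = t² identity. A
repeated-measures variant (within-subject error term) is provided for the
model-free table, whose published F statistics carry within-subject
denominator degrees of freedom. Reaction-time and performance summaries
compare treatments with paired t tests on per-subject means; percent correct
counts free choices of the option with the higher generative mean, excluding
zero-difference games.

## Parameter recovery

Recovery is the package's acceptance surface: simulate a full crossover
study (22 subjects × 2 treatments × 120 games) from the default populations,
fit it, and require (a) the fitted population decision-noise ordering
σ(h6), σ(h11) > σ(h1) in every treatment × information cell, (b) pooled 95%
credible-interval coverage of the generating population parameters within
[0.85, 0.99], and (c) Spearman correlation > 0.7 between true and
posterior-mean subject noise. The test suite runs three replicates with two
chains and 2500 post-burn-in sweeps (thin 5); a pilot at the full default
schedule gave the same qualitative picture (coverage 0.90, rank correlation
0.77, ordering 4/4). The `recover` CLI subcommand runs arbitrary replicate
counts at any schedule.

## What the synthetic data do and do not show

The generator emulates the published design and the published group-level
noise estimates, with choices drawn from the same model family that is fit —
so passing recovery demonstrates the estimation machinery is correct and the
design is informative, not that the model describes human behavior. Real
data bring model misspecification (learning within games, lapses,
sequential effects, RT–choice coupling) that no test here touches. The
published human F statistics and group tables depend on an undeposited
dataset and are reproduced only directionally (exploration rising with
horizon and with unequal information), never numerically.

## Known limitations

- k and λ are individually the slowest-mixing parameters (they are weakly
  identified by 22 subjects); their product, the reported population mean of
  σ, mixes well. Warnings name any parameter whose split R-hat exceeds 1.1.
- Cells whose true σ is large are weakly identified (a flat choice curve
  looks the same for σ = 10 and σ = 16 at the task's reward ranges);
  recovery intervals there are honest but wide, and occasionally miss.
- The between-cells ANOVA on subject-level posterior means inherits the
  shrinkage caveat: hierarchical estimates underestimate between-subject
  variance, biasing such F tests liberal. The package exposes both
  subject-level means and population-level medians so users can run the
  analysis they defend.
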