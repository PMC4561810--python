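# Methods

`hawkdove` models trial-by-trial choice in an iterated two-player chicken
(hawk–dove) game. Each trial both players simultaneously either **avoid**
(swerve) or **rush**. Mutual avoidance pays nothing to either player; when
exactly one player rushes, the avoider transfers a fixed amount to the
rusher; mutual rushing (a crash) costs each player more than the lone avoider
loses. The package simulates games under three trial-level utility models,
fits those models to observed records by maximum likelihood, compares them by
BIC against a chance baseline, classifies dyads into behavioral patterns
against simulation-calibrated thresholds, and traces non-stationary parameter
trajectories in sliding trial windows.

## The reward structure

Payoffs are configurable (`PayoffMatrix`). Defaults, in KRW:

| | opponent avoids | opponent rushes |
|---|---|---|
| **avoid** | 0 | −500 |
| **rush** | +500 | −1000 |

Two considerations fix these values. First, the kindness normalization
(below) yields kindness values of exactly ±1 — the values the three models
assume for this game — if and only if the crash cost is twice the lone
avoider's loss, which pins the crash/transfer ratio at 2. Second, the
absolute level only enters the models through the ratio of payoffs to the
`scale` parameter (default 1000 KRW per internal unit); transfer = 500 at
scale 1000 (internal 0.5) is the level at which simulations from the
reference pattern parameters best reproduce the published pattern-count
statistics (see *Calibration* below). With raw KRW the CES utilities would
saturate the sigmoid choice rule and play would be nearly deterministic,
which the published statistics rule out.

## Expected totals

Before choosing, a player evaluates each candidate action `a` by the expected
total reward for both players: the player's cumulative realized payoff over
trials `1..t−1` plus the current trial's payoff under `a`, averaged uniformly
over the opponent's two actions (the models hold no belief about the opponent
beyond that uniform average). With the default payoffs the expected own
increment is −transfer/2 for both actions, so the *own*-payoff term never
favours one action; all action preference comes from the other-regarding
terms.

## The three utility models

**Fehr–Schmidt inequity aversion (`fs`).** Utility is the own expected total
minus a penalty on the payoff gap: weight `alpha ∈ [0, 10]` when behind,
`beta ∈ [0, 1)` with `beta ≤ alpha` when ahead. The joint constraint is
enforced by reparameterization during both sampling and optimization
(`beta = s · min(alpha, 1−ε)`, `s ∈ [0, 1]`), so bounded optimizers never
leave the feasible set. With `alpha = beta = 0` the model reduces to a pure
expected-own-payoff maximizer, which under the default payoffs predicts every
action at probability one half.

**Kindness.** The kindness of an action is the other player's best attainable
payoff under that action, mean-centered over the actor's actions and
normalized by the mean payoff range. In the chicken game avoiding is +1 and
rushing −1 (exactly, given crash = 2·transfer).

**Cox-style reciprocity (`cox`).** An emotional state `theta` weights the
opponent's expected total inside a CES utility
`u = (1/α)(pow*(own, α) + θ · pow*(other, α))` with convexity
`alpha ∈ (0, 1]`. The state retains a fraction `gamma ∈ [0, 1]` per trial,
absorbs the opponent's kindness scaled by sensitivity `delta ∈ [0, 1]`, and
adds a benevolence bias `beta ∈ [−1, 1]` every trial. The original model's
relative-status term is deliberately absent: the game is symmetric, so no
status difference is definable.

**Self-concept (`sc`).** The player keeps two kindness ledgers — its own
accumulated kindness `F_self` and the opponent's as perceived `F_other`
(biased by `beta`, which enters `F_other` only) — and the CES weight is the
reciprocity `r = 2(δ·F_other − (1−δ)·F_self)`. At `delta = 0.5` this is the
plain ledger difference. Positive `r` inclines the player to help; a player
who has been kinder than the opponent (`F_self > F_other`) develops negative
reciprocity — the moral-licensing dynamic that distinguishes this model.

**Signed power.** Cumulative chicken payoffs can be negative, where `x^α` is
undefined for non-integer `α`; the CES power is therefore the odd extension
`sign(x)·|x|^α`. An additive endowment offset was considered and rejected:
it adds a parameter the data cannot identify.

**Choice rule.** `p(avoid) = sigmoid(u(avoid) − u(rush))`, computed in a
saturation-safe form. The trial-1 state is zero for every model and no
burn-in trials are added.

## State-update rules (the central ambiguity)

The recursion "retained state + incoming kindness + benevolence" admits two
readings that differ sharply at high retention, and the package implements
both (`update_rule=`):

- **`smooth`** (default): kindness inputs are exponentially smoothed,
  `θ ← γθ + (1−γ)·δ·f + β` (and `(1−γ)·f` into the two `sc` ledgers), so the
  kindness component of the state stays on the ±1 scale of `f` for every
  retention rate, while the benevolence bias accumulates toward `β/(1−γ)`.
- **`accumulate`**: the raw accumulator `θ ← γθ + δ·f + β`; at `γ = 1` the
  states are running sums of kindness.

The two coincide at `γ = 0`. The default is `smooth` because it is the
reading under which the reference simulations reproduce the published
statistics (next section); under `accumulate`, a player facing a persistent
rusher always develops negative reciprocity regardless of benevolence
(the own-kindness ledger grows like `1/(1−γ)` and overwhelms the
β-augmented opponent ledger), so the one-sided "unfair" pattern cannot
persist — contradicting the published simulations in which extreme opposite
benevolence sustains it. The fitting and simulation sides always share one
rule; mixing rules between generator and estimator invalidates parameter
recovery.

## Calibration of the study conditions

The reference parameter sets (`hawkdove.reference.PATTERN_PARAMS`) are the
published average fitted values per behavioral pattern. The package's default
payoff level and update rule were chosen, once, as the configuration that
best reproduces two published summaries jointly: the mean two-trial-window
counts from 10,000 self-concept simulations at the reference parameters
(switching 43.12, mutual avoidance 66.11, mutual rush 46.29, unfair 55.28),
and the random-parameter classification thresholds (24, 22, 23, 20). A
factorial search over the documented ambiguity space (update-rule variants ×
payoff scale × history inclusion × rusher-gain asymmetry) found no
configuration that reproduces all eight numbers simultaneously. The chosen
defaults reproduce the switching and mutual-rush means within 1 SD (43.7 and
44.9) and the mutual-rush and unfair thresholds within ±3 (23 and 22); the
mutual-avoidance and unfair means (observed ≈ 36.5 and ≈ 29.3) and the
switching and mutual-avoidance thresholds (observed 29 and ≈ 52) are not
reproducible at any point of that space and are reported as-is by
`scripts/acceptance.py`. The residual discrepancy indicates that the original
simulations differed from the printed recursions in some further unstated
way; rather than invent an unprincipled variant, the package keeps the two
defensible rules and documents the gap.

## Pattern counting, thresholds and classification

Patterns are counted over **overlapping** two-trial windows (stride 1; 99
windows per 100 trials): *switching* (exactly one rusher per trial, identity
swaps), *mutual rush*, *mutual avoidance*, and *unfair* (same lone rusher in
both trials). Thresholds are calibrated by simulating self-concept games with
both agents' parameters drawn independently and uniformly over their bounds
and taking the upper-5% order statistic of each pattern count (the published
run used 10⁶ games; `derive_thresholds` defaults are equivalent at ≥10⁵).
Independent draws per agent were chosen over a shared draw as the less
structured null — a shared draw makes symmetric sustained patterns far too
easy and pushes the avoidance cutoff toward 99. A dyad is classified to the
pattern whose count meets or exceeds its cutoff; among several, greatest
excess wins, with ties broken switching → mutual avoidance → mutual rush →
unfair (deterministic and rarely triggered at the reference cutoffs).

## Fitting and model comparison

Player `i`'s likelihood depends only on player `i`'s parameters given the
observed joint history, so the two players are maximized separately
(L-BFGS-B, bounds as above, 20 uniform random starts by default, ties to the
first-found best; convergence `ftol` 1e-9, ≤500 iterations per start). The
per-player replay is JIT-compiled with numba when available and falls back to
pure Python otherwise. `BIC = −2 logL + k·ln(n_trials)` with `k` counting
both players' parameters (4/8/8) since the likelihood sums both players. The
chance baseline predicts every action at probability 0.5: BIC
`−2·2·n·ln(0.5)` = 277.26 for 100 trials. Comparison tables report
per-pattern and overall mean/SD BIC with paired t-tests against the baseline
and between models; single-member groups get descriptive rows only.
Single-action (all-avoid/all-rush) players are fitted as-is and flagged when
estimates sit on a bound, never clipped silently.

## Non-stationary (sliding-window) analysis

The model is refitted in every stride-1 window of 20 trials (81 windows per
100-trial game; window BIC uses n = 20). Each window's optimizer warm-starts
from the previous window's solution plus fresh random starts — faster and
smoother than independent restarts. Per window, the absolute between-player
difference of each parameter and the fit quality (−logL, an affine function
of window BIC at fixed window size — their Pearson correlations are
identical) form the convergence diagnostics: a two-sample t-test compares the
first half of the window series against the second (81 windows split 40/40,
middle dropped; negative t = converging rules), and Pearson r relates each
difference trajectory to fit quality (positive r = the model predicts better
when the players' rules are closer). Overlapping windows are autocorrelated;
the p-values are descriptive, not inferential, and the outputs say so.
Multiple dyads of one pattern can be pooled by averaging difference series
window-wise (`pool_diff_series`, mode `mean`) or analyzed per dyad
(`concat`); both modes exist because the published aggregation is not
stated.

## Synthetic data: what it does and does not emulate

The generator plays model-driven agents against each other under exactly the
utilities and choice rule the fitting side assumes, with seeded,
batch-vectorized draws (a master `SeedSequence` spawns per-batch children;
ensembles of 10⁴–10⁶ games run in seconds to tens of seconds on one CPU). A
per-trial parameter-trajectory hook (`simulate_nonstationary_pair`,
`linear_trajectory`) emulates players whose rules drift or converge during a
session. Passing tests on these data shows internal consistency — parameter
recovery, pattern statistics, convergence detection — under the package's own
generative assumptions. It does not show that human players follow any of the
three models, does not reproduce individual-dyad idiosyncrasies (reaction
times, fatigue, within-trial timing collapsed to a binary choice), and the
published human-data tables (per-pattern BIC values, prevalence such as 12/36
switching dyads) are not recomputable because the behavioral data were never
deposited.

## Problem sizes and numerical choices

Reference reproductions use 10,000-game ensembles and a 100,000-game
threshold run — large enough that Monte-Carlo error (≈0.07 windows on an
ensemble mean; ±1 on a cutoff) is far below the comparison tolerances, small
enough to run in seconds. Parameter-recovery checks pool 100- vs
1,000-trial records; recovery error roughly halves over that range.
Convergence-calibration experiments use 200 replicate games (100 forced
convergent, 100 stationary) with 2-start warm-started window fits.
Degenerate inputs are handled explicitly: zero-variance difference series
make the half-split test and correlation undefined and are flagged rather
than silently dropped; saturating sigmoid arguments use log1p forms; the
order-statistic threshold requires enough simulations for the requested
quantile and errors otherwise.

## Known limitations

- The published pattern statistics are only partially reproducible (see
  *Calibration*); four of the eight reference numbers disagree beyond
  tolerance under every defensible reading of the recursions.
- The `fs` reference rows are averages that violate `beta ≤ alpha` and
  cannot be used as validated parameter objects.
- Window-level inference ignores autocorrelation by design (matching the
  analysis it implements); treat those p-values as descriptive.
- The optimizer is a multi-start local search; with 20 starts the best
  optimum is stable across seeds on 100-trial records, but global optimality
  is not guaranteed on 20-trial windows, where the likelihood can be nearly
  flat (saturated play leaves parameters unidentified).
- Convergence detection from 20-trial window fits has limited power: in the
  package's 100+100-replicate calibration, forced-convergence dyads are
  flagged in a majority of replicates (~0.6) and stationary dyads in a small
  minority (~0.14), but requiring a jointly significant difference-fit
  correlation caps detection near 60% because window-MLE noise dilutes the
  fit-quality trajectory.
  Weakly expressed rules are a hard floor here: near-chance play is best fit
  by near-zero-signal parameters for *both* players, so genuinely different
  but weak rules look similar to the estimator.
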