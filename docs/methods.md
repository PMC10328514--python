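# Methods

`valuecode` implements an analysis pipeline for cue, lick, reward, value,
and history coding in event-aligned neural activity from an olfactory
Pavlovian conditioning task, together with a synthetic session generator
that supplies ground truth for every analysis. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## The task and the synthetic generator

A session presents six odor cues: two odor sets (A, B) of three cues each,
predicting reward with probability 1 (CS+), 0.5 (CS50), or 0 (CS−). The
default electrophysiology-style layout runs six blocks of 51 trials with
alternating odor sets (306 trials, 51 per cue), rewards delivered 2.5 s
after odor onset, and inter-trial intervals drawn uniformly from 8–12 s.
CS50 rewards follow an exact-half schedule, randomly permuted within each
cue (26 of 51), so reward-history regressors have full support; the
counterbalancing rule is an assumption, stated here because the protocol
only fixes the probability.

Generative trial value is the nominal cue value plus an optional same-cue
history term: a sum over the previous 10 same-cue outcomes, centered on
the cue's reward probability, with exponential decay (`history_tau` = 3
trials) and weight `history_weight` (default 0; the history studies use
0.5). Centering makes the term vanish for CS+ and CS− (whose outcomes are
deterministic), concentrating history effects in CS50 trials, as in real
behavior.

Licking is an inhomogeneous Poisson process: a 0.3 licks/s baseline, an
anticipatory ramp from cue onset to reward time whose endpoint is
7 licks/s times the trial value, and a consummatory burst (7 licks/s for
2 s) whose first lick is guaranteed 0.08–0.25 s after reward delivery so
that consumption onsets exist on every rewarded trial. Lick trains are
debounced at a minimum interlick interval of exactly 1/12 s. The detector
constraint is usually quoted as 0.083 s with a 12 licks/s cap; a literal
0.083 s threshold would admit 13 licks in a second (12 × 0.083 = 0.996 s),
so the cap itself is taken as the definition. A lick bout starts at any
lick preceded by at least 0.5 s of silence.

Each neuron's instantaneous rate is

    rate(t) = max(0, baseline + cue_gain · s_t · k_cue(t − t_cue)
                     + lick_gain · Σ k_lick(t − t_lick)
                     + reward_gain · k_reward(t − t_consumption))

with Poisson spikes in 1 ms bins (or Gaussian-noise traces at 15 Hz in
trace mode). `s_t` is the neuron's tuning value for the trial's cue
(a vector in {0, 0.5, 1}^6), shifted toward the generative trial value in
proportion to `history_gain`. Cue kernels are per-neuron mixtures of two
gamma-shaped bumps with random peak times (0.2–1.0 s and 0.8–2.2 s) and a
random late-bump weight: real neurons have individually distinctive
response shapes, and the cross-day identity analysis is only meaningful if
the generator reproduces that distinctiveness. Reference signal-to-noise:
cue_gain 10, lick_gain 5, reward_gain 10 events/s at the kernel peak over
a 2–8 events/s baseline. These defaults are the conditions under which the
recovery guarantees in the test suite are stated.

What the generator does not emulate: biophysical spiking (no refractory
period, no bursting), calcium indicator dynamics, slow drift in
excitability, correlated noise across neurons, and movement artifacts.
Passing recovery tests therefore shows that the pipeline is correct and
calibrated under its own assumptions, not that real recordings will reach
the same sensitivity.

## Binning, smoothing, and PSTHs

Spikes are counted in 0.02 s bins and smoothed with a causal half-normal
filter (σ = 300 ms, 50 taps, normalized to unit sum; weights supported
only on present and past bins). Lick PSTHs use σ = 800 ms. PSTHs are
built in 0.1 s bins around cue onset (resampling from 0.02 s bins is by
mean, preserving rate units) and z-scored per neuron against the pooled
0.1 s bins in the 2 s before every trial; zero-SD neurons are flagged and
zeroed rather than producing infinities. Bin edges are half-open
[t, t + Δ) with bin 0 starting exactly at cue onset. Response polarity is
decided on even trials (peak-magnitude deviation in 0–2.5 s; an exact tie
goes to "above") so that odd-trial summaries are cross-validated.

## Design matrices

Predictors are Toeplitz stripe matrices at 0.1 s bins over concatenated
per-trial windows (−1 to 6.5 s for the full model; −1 to 2.5 s for the
restricted cues+licks model). Events falling between trial windows are
dropped, and stripes are truncated at window boundaries. The full model
holds six cue kernels (0–5 s), a lick kernel (−0.3–0.3 s), a bout-start
kernel (−0.3–2 s), six copies of the session-long smoothed lick rate
time-shifted by −0.4 … 0.6 s in 0.2 s steps, a reward kernel (0–4 s
from the first lick after reward delivery), and one constant per block —
381 columns. Block constants absorb tonic rate changes so cue kernels
cannot explain baseline shifts across blocks. In the restricted model cue
kernels are limited to 0–2.5 s (rows end at 2.5 s, so longer lags would
have no support). Value-scaled designs replace the six cue kernels by a
single kernel whose stripe height is the trial's value.

The lick-rate regressor is smoothed at the source rate with a 25-tap
causal half-normal, resampled to 0.1 s, and shifted so that the column for
shift s at row time t holds the rate at t − s.

## Reduced-rank elastic-net regression

The kernel matrix K (381 × N) is factorized as K = B·W with rank r = 20.
B comes from the Izenman construction: ridge-stabilized least squares K₀
(ridge 1e-8 relative to the mean Gram diagonal, for invertibility only),
SVD of the fitted values P·K₀, and B = K₀·V[:, :r]. Per-neuron weights on
the projected predictors P·B are fit with elastic-net regularization —
penalty λ·(α‖w‖₁ + (1−α)‖w‖₂²/2), α = 0.5, λ selected per neuron from
{0.001, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5} — by fourfold
cross-validation at the trial level, stratified by cue; ties in held-out
error go to the larger λ. Columns are standardized before penalization;
variance explained is 1 − SSE/SStot pooled over held-out bins (it can be
negative). Zero-variance targets are assigned exactly 0.

One deliberate deviation from the obvious implementation: the rank basis
is re-estimated inside each training fold rather than once on all rows.
With populations of hundreds of neurons the difference is negligible, but
with tens of neurons a basis computed from all rows contains each
neuron's own held-out activity, and pure-noise neurons inflate past the
2% selection gate. Per-fold basis estimation restores an honest null
(noise neurons score ≤ 0) and is what makes the cutoff calibration below
achievable at small population sizes. Final reported kernels use a basis
from all rows.

The solver is an in-package cyclic coordinate descent on precomputed Gram
matrices, vectorized over all neurons sharing a design (convergence
tolerance 1e-4 on the largest coefficient update). This is what makes the
~10⁴ small refits (cross-validation grids, 153 tuning models, permutation
nulls) affordable; it is verified against scikit-learn's ElasticNet to
1e-6 in the test suite.

### Unique variance and classification

A neuron codes cues, licks, or reward if removing that predictor group
(refitting the reduced design, rank basis recomputed) costs more than 2%
of cross-validated variance explained and the full model exceeds 2%.
The cutoff is calibrated by a misalignment control: each trial's activity
segment is reassigned to a random other trial's rows *and* circularly
shifted within the window. The shift matters — every trial window
contains a cue at the same within-window latency, so a bare permutation
leaves stereotyped cue-locked responses fittable by the cue kernels and
could never yield zero false positives; the within-window shift is what
actually decouples activity from every event family while preserving
per-neuron totals. At the 2% cutoff, 60 neurons, and 306 trials, ten
shuffles label no neurons.

## Cue-tuning models

153 candidate tuning vectors over the six cues: the 90 distinct
permutations of {1, 1, 0.5, 0.5, 0, 0} (including the ranked value model
(1, 0.5, 0, 1, 0.5, 0)) and the 63 binary patterns with k of 6 cues at 1
(including the all-ones untuned model). Each model's Pearson correlation
with the ranked model defines its category: the ranked model itself;
untuned (the constant vector, whose correlation is undefined and which is
categorized directly); value-like (r > 0.5; 26 models); other (125).
Models are fit to cue-only neurons (cue label without lick label under
the restricted design) as a single value-scaled cue kernel plus block
constants at full rank, scored by cross-validated variance explained, and
the best model is chosen per neuron (ties broken toward fewer distinct
value levels, then lower model id — both arbitrary but fixed). Neurons
whose best model is the ranked model are confirmed as value neurons only
if their score exceeds the 98th percentile of a null built by refitting
under random permutations of the value multiset over cues; a permutation
equal to the identity contributes the true score, and percentiles use
strict exceedance. Null permutation draws are shared across neurons in a
batch (each neuron's null remains a valid exchangeability null; only
cross-neuron independence of the draws is given up, which no reported
quantity uses).

## Trial value and the history model

Anticipatory licks (0–2.5 s from odor onset, half-open so reward-driven
licks at exactly 2.5 s are excluded) are normalized so each session's
maximum is 1 and regressed on cue identity (six indicators), reward
outcomes on the previous 10 trials of any cue, outcomes on the previous
10 trials of the same cue, and the cue's cumulative presentation count
(satiety), by ordinary least squares jointly across sessions. History
regressors are zero-padded at session start. The model's per-trial
prediction v_t is the trial value; on generator sessions with history its
per-cue means land near 0.05 / 0.35 / 0.6 for CS− / CS50 / CS+.
Predictions can dip slightly below zero on CS− trials and are clipped at
0 before use as kernel scalings.

The history model scales a single cue kernel by v_t. Value and value-like
neurons whose history-model score beats all 153 static models are
candidates; they are flagged as history neurons if the true score exceeds
the 95th percentile of a null with v_t permuted within each cue (which
preserves each cue's value distribution while destroying its link to
specific trials). A licks-only model (restricted design minus cue
columns) provides the comparison score for asking whether licking or
history better explains such neurons.

## Decoding

Single-neuron cue identity: six-way linear discriminant per 0.25 s bin
from −0.5 to 2.5 s, 50 trials per cue, fivefold stratified
cross-validation. Ensemble decoding pools activity 1–2.5 s from onset,
assembles pseudo-trials by resampling trial indices independently per
neuron within cue (neurons were not recorded simultaneously), and uses a
Gaussian discriminant whose pooled covariance is shrunk fully to its
diagonal (γ = 1); accuracy distributions come from 1000 bootstrap neuron
selections at sizes {1, 5, 10, 25, 50, 75, 100, 200}.

Value decoding regresses cue value (0/0.5/1) on pooled activity with an
elastic net (α = 0.5), trained on a balanced composition that excludes
every trial of the held-out cue: all 50 same-value trials come from the
other odor set, and the other two value classes contribute 25 trials per
set. λ is selected by fivefold cross-validation from the standard grid
extended with 0 (the OLS limit), so noiseless linear populations predict
exactly. Predictions are banded — CS− [−0.25, 0.25), CS50 [0.25, 0.75),
CS+ [0.75, 1.25], edges going to the lower band, values outside all bands
incorrect. Bootstrap comparisons use one-way exceedance fractions (ties
count toward both directions) with Bonferroni correction.

## Coding-dimension geometry

PSTHs are max-normalized per neuron (concatenated six-cue PSTH peaking at
±1, sign preserved). From even trials, each neuron's peak-difference
0.5 s bin (tiled bins {0–0.5, …, 2–2.5 s}; tiled rather than sliding, a
flagged choice) between the high and low cue defines a signed difference
vector d; multiplying d against the original z-scored peak-bin states of
the two defining cues gives the constants mapping projections to a 0
(CS−) to 1 (CS+) scale. Odd-trial activity, other-odor-set activity, or
per-trial activity is then projected. The CS+/CS50 trajectory angle is
computed in the plane of the (CS−/CS+, CS−/CS50) projections from the
vectors connecting the pre-cue baseline point to the farthest trajectory
point in 0–2.5 s, in degrees, bootstrapping neurons with replacement
(5000 iterations, both dimensions rebuilt per resample). The value slope
regresses mean 1–2.5 s projections of CS50 trials on their lick-model
trial values, again with a 5000-iteration neuron bootstrap.

## Cross-session stability

For populations with matched neuron identities, (1) each neuron's
concatenated per-cue PSTH on day n is correlated with every neuron's
profile on day n+1; the self-match percentile among correlations with the
other neurons (100 = more correlated with itself than with anyone else)
is compared with an identity-shuffled control by Wilcoxon signed-rank.
This analysis is only informative for neurons with distinctive
event-locked shapes; pure-noise neurons sit at chance by construction.
(2) Kernels fit on one session predict other sessions from their own
event times; per-neuron prediction correlations per session third are
normalized by the training session's cross-validated correlation and
compared with a trial-shuffle control that preserves within-trial
temporal structure (so lick-locked components retain some accuracy, as
expected). (3) Unique variance is refit independently per day for cells
categorized on a reference session.

## Problem sizes and defaults in the test suite

The suite exercises the full pipeline at 60 neurons × 306 trials
(cutoff calibration), 50 neurons × 306 trials (value/untuned recovery
with a 200-iteration null), 200 neurons × 306 trials (history recovery
with a 100-iteration null), 40-neuron populations for geometry (5000
bootstraps), and three 102-trial sessions of 30 tracked neurons for
stability. Unit tests use 72-trial sessions. These sizes are the
package's own reference conditions; the statistical rules (2% cutoff,
98th/95th percentile nulls, band edges, λ grid) are fixed constants of
the method.

## Known limitations

- The generator's lick and reward kernels are shared across neurons, so
  cross-day identity is carried by cue kernels; lick/reward cells are
  identifiable by category but not individually distinctive.
- The trial-value model is descriptive (linear in history indicators);
  no latent-value or reinforcement-learning model is fit.
- Calcium-trace mode applies the resampled smoothing filter to
  noise-added rates; indicator kinetics and deconvolution artifacts are
  out of scope.
- Permutation nulls share draws across neurons within a batch (see
  above); per-neuron callers can pass distinct seeds where independence
  across neurons matters.
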