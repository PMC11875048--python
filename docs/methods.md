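# Methods

`shiftsim` is a hardware-free, seeded discrete-event re-implementation of the
control logic of a head-fixed cross-modal attentional set-shifting task for
mice, together with the behavioral analytics used to characterize performance
in that task. This note documents the model, its parameters and defaults, the
synthetic-behavior generator, the numerical conventions, and the limits of
what the simulations can show.

## The task

On each trial of the two-alternative forced choice (2AFC), a head-fixed mouse
receives a whisker-vibration stimulus and/or an odorant and reports a decision
by licking the left or right water spout. Two latent exemplar→side maps (one
per modality) define which side each cue predicts; a covert rule names the
*relevant* modality. A trial is **congruent** when both maps send the
presented exemplars to the same side — only incongruent trials require the
active attention rule to respond correctly. Congruency is defined purely by
the latent maps and is independent of which modality is currently relevant.

Trial timing (task stages): a 500 ms white-noise tone signals trial onset;
the stimulus epoch (2,500 ms) begins at tone offset; the response window
(1,500 ms) opens at stimulus offset, i.e. 2.5 s after stimulus onset. The
tone and stimulus are modeled as sequential (configurable), which makes the
stimulus-onset-to-response-window interval exactly `stim_ms`. Odorant arrival
at the nose lags the valve command by 120 ms; passive odor clearing is logged
2,000 ms after stimulus offset as bookkeeping. Licks during the stimulus
epoch are recorded (anticipatory licking) but never rewarded; only
response-window licks enter the reward rule. Rewards are 4 µl droplets
delivered at the time of the qualifying lick, after which the trial proceeds
straight to the intertrial interval (ITI). ITIs are drawn uniformly over
3,000–4,500 ms in shaping and 8,000–10,000 ms from simple discrimination
onward; habituation uses a 500–1,500 ms post-reward timeout.

Time is integer milliseconds from session start; all intervals are drawn as
integers uniformly and inclusively over their configured ranges, so a session
is bit-reproducible from its seed with no floating-point drift.

## Curriculum

Stages run HB1 → HB2 → HB3 → HB3B → SH4 → SH5 → SD → CD → set-shifting, each
repeating until passed:

| stage | schedule | stimuli | reward rule | pass criterion |
|---|---|---|---|---|
| HB1/HB2 | pseudorandom armed side | none | any lick to armed side | 500 µl consumed |
| HB3/HB3B | blocks of 5, 10, 15, 20, 20… per side | none (HB3B: post-lick whisker flash 150–300 ms) | any correct lick | 500 µl |
| SH4 | 20-trial side blocks | whisker | any correct response-window lick | 500 µl |
| SH5 | 20-trial side blocks | whisker | first lick must be correct | 80 % in a 100-trial window |
| SD | randomized (± bias correction) | whisker | first lick | fourfold (below) |
| CD | randomized | whisker + odor distractor | first lick | fourfold |

The fourfold discrimination criterion: (1) more than 100 trials, (2) 80 %
accuracy in a 30-trial moving window, (3) one 10-trial window in which left-
and right-trial accuracy simultaneously exceed 50 %, and (4) a response on
more than 80 % of trials. Accuracy thresholds are inclusive ("reach 80 %" is
attainment: 24/30 fires), and all accuracy windows run over *response* trials
only; no-response trials count only toward response rate. Both conventions
are package-wide.

Sessions terminate on the first satisfied condition: 10 consecutive
no-response trials (satiety), the configured consumed-volume target
(habituation/SH4), a trial cap (default 2,000, a guard not part of the
protocol), or — HB1/HB2 only — 2 minutes without a reward (recorded as
`manual`, standing for the experimenter ending the session). When volume
target and the 2-minute rule could fire together the per-trial check order
(omissions, volume, cap, timeout) decides; in practice a rewarded trial
resets the timeout so the volume target dominates.

In `run_curriculum`, session *k* (global index) runs on the RNG stream
`numpy.random.default_rng([seed, k])`, so any single session can be
reproduced in isolation.

## Set-shifting control

In serial set-shifting (SEDS) sessions the rewarded side is drawn each trial
— fair coin, or with lick-bias correction enabled, `P(left)` equals the
fraction of *right* responses among the last 20 response trials, clamped to
[0.1, 0.9] (window and clamp are explicit configuration; only the
inverse-relation principle is fixed). The relevant modality's exemplar is the
one mapping to the drawn side; the distractor exemplar is drawn uniformly, so
congruent and incongruent trials each occur at rate ½.

A covert rule switch fires at the first trial where the current block's
trailing 30 response trials reach 80 % accuracy (trailing-window evaluation
is equivalent to first attainment and cheaper; no-response trials are
excluded, consistent with the accuracy convention). Three transformations are
supported: **Rev** swaps the relevant pair's sides; **EDS** toggles the
relevant modality and leaves both maps untouched (hence congruency labels are
invariant under EDS); **IDS** replaces the relevant pair with two
session-fresh exemplars from that modality's pool (error when fewer than two
remain). The default shift sequence alternates EDS indefinitely; arbitrary
sequences are accepted and cycled. A "block" is the run of trials between
consecutive switches plus the terminal partial block.

## The simulated mouse

The agent is a deliberately minimal mechanism producing every phenomenon the
analytics must detect; no claim is made that its parameters correspond to
mouse cognition.

Choice: respond with probability `p_respond`; given a response, lapse to a
uniform side with probability `lapse`; otherwise the decision variable is

    evidence = w · assoc[whisker] + (1 − w) · assoc[odor],

with signed association strengths in [−1, +1] (+1 = right), an absent
stimulus contributing nothing (weight renormalized away), and
`P(right) = logistic(inv_temp · evidence + side_bias)`.

Learning (response trials only): each presented exemplar's strength moves
toward the signed rewarded side by `assoc_lr · (target − strength)` — the
update uses the trial's rewarded side because an animal that licks the wrong
spout and receives nothing can infer where the water was. Attention moves
toward a modality (by `attn_lr`, complementary weights) only when exactly one
presented modality's association sign agreed with the outcome: congruent
trials carry no information about the relevant modality and leave attention
unchanged. This confines perseveration to incongruent trials after covert
switches, which is the structure the switch-aligned analysis assumes.

Closed forms used as oracles: a saturated agent (both maps learned, all
attention on one modality, near-infinite `inv_temp`) is correct on congruent
trials unless it lapses to the wrong side — accuracy `1 − λ/2` — and, right
after an EDS with no relearning, wrong on every incongruent trial unless it
lapses luckily — accuracy `λ/2`, below chance.

Anticipatory licking runs at `lick_rate_hz` (default 8 Hz; reported lick
rhythms span roughly 6–10 Hz and 8 is the overlap) with ±8 % timing jitter,
mostly toward the eventual choice, from stimulus onset to the response lick,
which falls 100–500 ms into the response window. Satiety is a per-session
normal draw (mean `satiety_trials`, SD 50, truncated at 1); past it the
response probability drops to zero, so the 10-omission termination arises
naturally. Within `run_session` trials continue after satiety onset so that
termination can fire; calling `run_trial` directly on a satiated agent is an
error.

Default cohort parameter ranges (`DEFAULT_COHORT_RANGES`) draw moderate
learners with mild side bias and satiety between 250 and 650 trials, so
set-shifting sessions land at a few hundred trials with several switches each
— a realistic envelope, used as a calibration aid, not an acceptance claim.

## Analytics

* `moving_accuracy`, `trials_to_criterion`, `check_switch_trigger`, and the
  fourfold stage evaluation are all trailing-window statistics over response
  trials; each is verified exactly against exhaustive brute-force scans on
  random sequences.
* `segment_blocks` partitions a session at its `rule_switch` events;
  switch-offset indexing puts offset 0 at the first trial under the new rule
  (pre-window −10…−1, post-window 0…+9).
* `periswitch_anova` fits per-trial correctness (0/1) with a three-way
  fixed-effects ANOVA (modality × congruency × timing, pairwise interactions
  only) through statsmodels OLS. Unbalanced cells — inherent to peri-switch
  windows — use marginal (Type III) sums of squares with sum-to-zero
  contrasts by default; sequential SS is available. Calibration is checked
  two ways: exact agreement with a hand-computed balanced table, and a
  1,000-run null simulation whose per-effect type-I error must sit within
  Monte-Carlo error of the nominal 5 %. Post-hoc cell comparisons use Welch
  t-tests with Bonferroni correction across all pairs; zero-variance pairs
  are resolved by their means.
* `fit_agent` grid-searches `{lapse, attn_whisker0, inv_temp}` by replaying
  the logged trials deterministically (associations from zero, learning rates
  from supplied base parameters, state carried across sessions in log order)
  and maximizing the Bernoulli log-likelihood of the observed responses. The
  attention weight is identifiable only when both modalities' associations
  stay expressed; the recovery experiment therefore generates from a
  slow-association (`assoc_lr = 0.04`), static-attention (`attn_lr = 0`)
  agent, where the weight acts on every incongruent trial. With a fast
  association rate the distractor strength decays between switches and the
  likelihood profile over the weight is nearly flat.
* All analyses are pure functions: the same trial table yields bit-identical
  outputs.

## File formats

Events stream to JSON-lines (fixed key order `t_ms`, `kind`, `payload` with
sorted payload keys); trials to CSV with a fixed header; the manifest stores
the full configuration and its SHA-256 digest, which is re-verified on read.
Identical runs produce byte-identical bundles. Sides print as `"L"`/`"R"`;
timestamps are integers. Reading validates every trial's invariants and
reports corrupt rows and truncated lines by location. Bookkeeping events
whose natural time falls in the ITI (odor clearing, the habituation
reinforcement-tone offset) live only in the session-level stream, so no
event inside a trial follows its `trial_end`.

## Problem sizes

Default verification sizes: 1,000 random sequences (n ≤ 200) for the
window-statistic oracles; 100 simulated sessions for the switch audit;
10,000 trials per condition for the closed-form accuracy and bias-correction
checks; 1,000 null and 100 effect datasets for ANOVA calibration;
~2,200 trials for parameter recovery. These sizes put Monte-Carlo error well
inside each check's tolerance (3 binomial standard errors unless stated).

## Limitations

* No physical modeling of air flow, acoustics, solenoid dynamics, or real
  time; the clock is simulated and stimuli are symbolic exemplars.
* The agent omits motivational dynamics beyond a satiety cutoff, lick-rate
  acceleration, post-reward consummatory licking, and any within-trial
  evidence accumulation; passing tests show the *analytics* behave correctly
  on data with the assumed statistical structure, not that real mice do.
* SH5+ incorrect first licks carry no penalty timeout beyond the ITI.
* Rule switches are performance-triggered only; experimenter-chosen switch
  times are out of scope.
* The rank-sum comparison of trials-to-criterion across modality rules is
  implemented operationally; its p-values on simulated agents say nothing
  about animal data.
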