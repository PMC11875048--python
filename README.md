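# shiftsim

A seeded, hardware-free discrete-event simulator — plus the matching
behavioral analytics — for a head-fixed **cross-modal attentional
set-shifting task** in mice.

In the task, a head-fixed, water-restricted mouse reports a two-alternative
forced choice (2AFC) by licking a left or right spout. Each trial presents a
whisker-vibration stimulus and/or an odorant; latent exemplar→side maps
define which side each cue predicts, and a covert rule names the *relevant*
modality. After the animal reaches 80 % accuracy in a 30-trial moving window,
the rule switches without warning — a reversal (Rev), an intradimensional
shift (IDS), or an extradimensional shift (EDS) — and performance transiently
collapses on *incongruent* trials (where the two modalities point to opposite
sides) as the animal perseverates on the old rule.

`shiftsim` is for tool builders and analysts who need the task-control logic
as testable software: it re-expresses the full training curriculum
(habituation → shaping → simple/compound discrimination → serial
set-shifting), the trial state machine, bias-corrected reward scheduling, and
performance-triggered rule switching as a deterministic event-driven engine,
exercised by simulated mouse agents, with the standard analyses over the
resulting logs.

## The core quantities

* **Moving-window accuracy** over response trials; **trials to criterion**
  = response trials from block start until a windowed threshold (e.g. 80 % in
  20 or 30 trials) is first attained.
* **Switch-aligned accuracy**: trials indexed −10…+9 around each covert
  switch (offset 0 = first trial under the new rule).
* The **modality × congruency × timing** factorial summary of peri-switch
  correctness, with a three-way fixed-effects ANOVA (pairwise interactions,
  Type III sums of squares with sum-to-zero contrasts) and
  Bonferroni-corrected post-hoc cell comparisons.
* A generative **agent model**: attention-weighted associations
  `P(right) = logistic(inv_temp · [w·assoc_whisker + (1−w)·assoc_odor] + bias)`
  with lapses, trial-by-trial learning, anticipatory 8 Hz licking, and
  satiety — the simplest mechanism exhibiting acquisition, perseveration
  confined to incongruent trials, side bias, and session self-termination.

See `docs/methods.md` for the full model and conventions.

## Worked example

Simulate one serial set-shifting session for a competent learner and analyze
the resulting bundle:

```
$ cat agent.yaml
assoc_lr: 0.18
attn_lr: 0.12
inv_temp: 4.5
lapse: 0.03
satiety_trials: 300.0

$ shiftsim seds --agent agent.yaml --seed 7 --out run1
seed=7 stage=SEDS config_digest=86a0942fa1920f100a8b3b5491858bcc...
1 session(s), 310 trials, 9 rule switches -> run1

$ shiftsim analyze run1 --out report
 session stage_id  n_trials  n_response  response_rate  n_rewarded  total_volume_ul  n_switches  n_blocks   terminated_by
       0     SEDS       310         295       0.951613         239            956.0           9        10 no_response_run

switch-aligned cell table (modality x congruency x timing):
modality  congruency timing     mean       sd  n
    odor   congruent   post 0.863636 0.351250 22
    odor   congruent    pre 1.000000 0.000000 24
    odor incongruent   post 0.250000 0.440959 28
    odor incongruent    pre 0.937500 0.250000 16
 whisker   congruent   post 1.000000 0.000000 17
 whisker   congruent    pre 1.000000 0.000000 27
 whisker incongruent   post 0.318182 0.476731 22
 whisker incongruent    pre 1.000000 0.000000 22

periswitch three-way ANOVA (pairwise interactions):
                            ss     df          F             p
modality              0.169520    1.0   2.131927  1.460940e-01
congruency            4.912728    1.0  61.783815  4.100698e-13
timing                6.149693    1.0  77.340223  1.504478e-15
...
```

Reading it: the agent completed 310 trials (sessions end after 10 consecutive
no-response trials, the satiety signature), earning 956 µl across 239
rewards, and triggered 9 covert rule switches. Accuracy is near ceiling
before switches, collapses to ~0.25–0.32 on *incongruent* trials just after
them (perseveration, below the 0.5 chance level), and barely dips on
congruent trials — so congruency and timing are strongly significant while
modality is not, the signature of a modality-balanced set-shifting task.

The same things are available as a library:

```python
import numpy as np, shiftsim as ss
from shiftsim import analysis as an

agent = ss.make_agent(assoc_lr=0.18, inv_temp=4.5, lapse=0.03, satiety_trials=300.0)
log = ss.run_seds_session(ss.default_config("SEDS"), ss.default_rule(),
                          agent, rng=np.random.default_rng(7))
blocks = an.segment_blocks(log.trials, log.events)
anova = an.periswitch_anova(an.periswitch_table([blocks]))
```

Other subcommands: `shiftsim validate` (config lint), `shiftsim simulate`
(any single stage), `shiftsim curriculum` (the staged protocol end-to-end,
`HB1` through `CD`).

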