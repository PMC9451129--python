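# storynf

A fully simulated closed-loop narrative-interpretation neurofeedback
pipeline, for researchers designing or stress-testing decoded-neurofeedback
experiments.

The paradigm it models: participants listen to an ambiguous story that
supports two incompatible readings — Joanie is *cheating* on Arthur, or
Arthur is *paranoid*. At 7 predefined *stations* per run, a pre-trained
per-station logistic classifier decodes `p(c)`, the probability that the
listener currently holds the cheating interpretation, from their brain
activity (shifted 3 TRs for hemodynamic lag; TR = 1.5 s). The decoded
probability is normalized against a pilot cohort and converted into an
intermittent monetary reward that pushes each participant toward a randomly
assigned target interpretation, double-blind:

```
score_c      = (p(c) − μ_st) / (3 σ_st) + 0.5     clipped to [0, 1]
score_final  = score_c               (cheating group)
               1 − score_c           (paranoid group)
score_reward = score_final           if score_final > 0.5, else 0
```

`μ_st`, `σ_st` are the pilot mean and SD of `p(c)` at station *st*, so a
participant at the pilot mean scores exactly 0.5 and earns nothing: rewards
track deviation from the average interpretation trajectory in the assigned
direction. Per participant, *decoding accuracy* is the mean `p(c)` at
stations where they declared the cheating lens minus the mean where they
declared paranoid — a measure of how well the decoder tracks what the
listener says they are doing.

`storynf` replaces all neural data with a generative cohort model (two
activity templates, agents whose latent interpretation state shifts
patterns along the discriminant axis) and closes the loop with a
reinforcement-learning participant agent, so the entire procedure —
training, pilot normalization, 4 runs × 7 stations of probe/decode/reward,
yoked-control feedback, post-scan questionnaire scoring, and the
group-level analyses (group t-tests, decoding-accuracy correlations,
best/worst median split, Bonferroni correction) — runs end to end, seeded
and testable, in seconds. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
from storynf import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=1))
```

or `python examples/04_full_experiment.py`, which prints:

```
20 participants (10 cheating / 10 paranoid), 28 feedback events each

mean decoding accuracy: +0.224
decoding accuracy vs correct interpretation: r = 0.43, p = 0.056
interpretation by assigned group (one-tailed): t(18) = 7.02, p = 0.000

median split: 10 best decoders (5 cheating + 5 paranoid)
  best: mean correct interpretation = +0.909
  worst: mean correct interpretation = +0.655
```

Reading these numbers: across 20 simulated participants, decoded `p(c)` is
on average 0.22 higher at stations where the agent declared the cheating
lens than the paranoid lens (decoding works); participants with better
decoding accuracy end up with interpretation scores closer to their
randomly assigned target (positive r — the central individual-differences
effect of this design); and the within-group median split yields the
expected 5 + 5 best-decoding participants.

The other examples walk one capability each: the score transformation
(`01`), decoder training and pilot normalization (`02`), a single
closed-loop session (`03`), and yoked-control feedback (`05`).

A thin CLI mirrors the pipeline stages:

```sh
storynf run-experiment --seed 1 --out out/
storynf make-cohort / train-decoder / estimate-norms / run-session / score-behavior / analyze
```

Outputs are BIDS-inspired: per-participant events TSVs with JSON sidecars,
models as JSON, norms and analysis tables as TSV, every file stamped with
the config digest and seed for exact reproduction.

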